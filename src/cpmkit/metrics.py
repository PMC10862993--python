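"""Prediction-quality metrics and bootstrap confidence intervals.

Three metrics summarize observed vs. predicted outcomes: mean absolute
error (MAE, in outcome units), the Pearson correlation r, and the
cross-validated coefficient of determination

    R^2 = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar)^2

where ybar is the mean of the observed outcomes being evaluated. Unlike
r^2, this R^2 can be negative: predictions worse than the observed mean
give R^2 < 0. Percentile bootstrap intervals resample (observed, predicted)
pairs with replacement and recompute all three metrics per replicate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["MetricsReport", "mae", "cv_r2", "pearson_r", "bootstrap_ci", "compute_metrics"]


@dataclass
class MetricsReport:
    """Point metrics plus 95% bootstrap intervals for one model evaluation."""

    mae: float
    r: float
    r2: float
    ci_mae: tuple[float, float] | None = None
    ci_r: tuple[float, float] | None = None
    ci_r2: tuple[float, float] | None = None
    n: int = 0
    n_boot: int = 0
    level: float = 0.95
    seed: int | None = None
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        for name in ("ci_mae", "ci_r", "ci_r2"):
            ci = getattr(self, name)
            if ci is not None and ci[0] > ci[1]:
                raise ValueError(f"{name} interval must be ordered low <= high")

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def _check_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("observed and predicted must have equal length")
    if y.size == 0:
        raise ValueError("empty input")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("non-finite values in input")
    return y, yhat


def mae(y, yhat) -> float:
    """Mean absolute error, in the units of the outcome."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def cv_r2(y, yhat) -> float:
    """Cross-validated R^2 = 1 - SSE/SST; may be negative, never above 1.

    SST is taken around the mean of the observed values being evaluated
    (the pooled held-out outcomes, or the external test set).
    """
    y, yhat = _check_pair(y, yhat)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant observed outcome: R^2 undefined")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


def pearson_r(y, yhat) -> float:
    """Sample Pearson correlation between observed and predicted values."""
    y, yhat = _check_pair(y, yhat)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if y.std() == 0 or yhat.std() == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(np.corrcoef(y, yhat)[0, 1])


def bootstrap_ci(
    y,
    yhat,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> MetricsReport:
    """Percentile bootstrap intervals for MAE, r, and cross-validated R^2.

    Resamples (y_i, yhat_i) pairs with replacement; replicates whose
    resampled observed outcome is constant (r and R^2 undefined) are
    redrawn, up to 100 attempts each, so exactly ``n_boot`` replicates
    contribute. The count of redraws is recorded in the report.
    """
    y, yhat = _check_pair(y, yhat)
    n = y.size
    if n < 5:
        warnings.warn(
            f"bootstrap on n={n} pairs is unstable; intervals are indicative only",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    stats = np.empty((n_boot, 3))
    n_redrawn = 0
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            yb, pb = y[idx], yhat[idx]
            if yb.std() > 0 and pb.std() > 0:
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap replicate")
        stats[b] = (mae(yb, pb), pearson_r(yb, pb) if n >= 3 else np.nan, cv_r2(yb, pb))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha], axis=0)
    return MetricsReport(
        mae=mae(y, yhat),
        r=pearson_r(y, yhat),
        r2=cv_r2(y, yhat),
        ci_mae=(float(lo[0]), float(hi[0])),
        ci_r=(float(lo[1]), float(hi[1])),
        ci_r2=(float(lo[2]), float(hi[2])),
        n=n,
        n_boot=n_boot,
        level=level,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def compute_metrics(y, yhat) -> MetricsReport:
    """Point metrics only (no bootstrap)."""
    return MetricsReport(mae=mae(y, yhat), r=pearson_r(y, yhat), r2=cv_r2(y, yhat), n=np.size(y))
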