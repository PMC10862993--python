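"""Report generation: cohort comparison tables, metric-row rendering, and
run manifests for reproducibility."""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cohort_compare",
    "render_metrics_row",
    "parse_metrics_row",
    "RunManifest",
]

#: Continuous and binary phenotype columns compared between cohorts.
DEFAULT_CONTINUOUS = ("age", "outcome_baseline", "outcome_post", "fd_mean", "fd_pct_above")
DEFAULT_BINARY = ("sex",)


def cohort_compare(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    variables: list[str] | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Compare phenotype distributions between two cohorts.

    Continuous variables use a two-sample t-test (pooled variance by
    default; set ``equal_var=False`` for Welch); binary variables use a
    2x2 chi-squared test with Yates continuity correction. Returns one row
    per variable with the test statistic and p-value at full precision and
    rounded (2 decimals) for table rendering.
    """
    if len(table_a) == 0 or len(table_b) == 0:
        raise ValueError("both cohorts must be non-empty")
    if variables is None:
        variables = [
            v
            for v in (*DEFAULT_CONTINUOUS, *DEFAULT_BINARY)
            if v in table_a.columns and v in table_b.columns
        ]
    rows = []
    for var in variables:
        a = table_a[var].dropna()
        b = table_b[var].dropna()
        pooled = set(pd.unique(pd.concat([a, b])))
        if pooled <= {0, 1} and var not in DEFAULT_CONTINUOUS:
            counts = np.array(
                [
                    [(a == 0).sum(), (a == 1).sum()],
                    [(b == 0).sum(), (b == 1).sum()],
                ]
            )
            if np.any(counts.sum(axis=0) == 0):
                raise ValueError(f"variable {var!r} has an all-one-category level")
            res = stats.chi2_contingency(counts, correction=True)
            stat, p, test = float(res.statistic), float(res.pvalue), "chi2_yates"
        else:
            if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
                stat, p, test = 0.0, 1.0, "t_pooled" if equal_var else "t_welch"
            else:
                t_res = stats.ttest_ind(a, b, equal_var=equal_var)
                stat, p = float(t_res.statistic), float(t_res.pvalue)
                test = "t_pooled" if equal_var else "t_welch"
        rows.append(
            {
                "variable": var,
                "test": test,
                "statistic": stat,
                "p_value": p,
                "statistic_rounded": round(stat, 2),
                "p_value_rounded": round(p, 2),
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "n_a": int(a.size),
                "n_b": int(b.size),
            }
        )
    return pd.DataFrame(rows)


def _fmt_ci(value: float, ci: tuple[float, float] | None, digits: int = 4) -> str:
    def num(x: float) -> str:
        s = f"{x:.{digits}f}"
        return f"({s})" if x < 0 else s

    if ci is None:
        return num(value)
    return f"{num(value)}[{num(ci[0])}-{num(ci[1])}]"


def render_metrics_row(report, predictors: str, nuisance: str, digits: int = 4) -> str:
    """One tab-separated table row: Predictors, Nuisance, MAE, r, R^2.

    Each metric cell is ``value[low-high]`` with negative numbers wrapped
    in parentheses, matching the layout of a published results table.
    """
    cells = [
        predictors,
        nuisance,
        _fmt_ci(report.mae, report.ci_mae, digits),
        _fmt_ci(report.r, report.ci_r, digits),
        _fmt_ci(report.r2, report.ci_r2, digits),
    ]
    return "\t".join(cells)


_NUM = r"\(?(-?\d+\.?\d*)\)?"
_CELL = re.compile(rf"^{_NUM}(?:\[{_NUM}-{_NUM}\])?$")


def parse_metrics_row(row: str) -> dict:
    """Invert :func:`render_metrics_row` at rendered precision."""
    parts = row.split("\t")
    if len(parts) != 5:
        raise ValueError("expected 5 tab-separated cells")
    out = {"predictors": parts[0], "nuisance": parts[1]}
    for name, cell in zip(("mae", "r", "r2"), parts[2:]):
        m = _CELL.match(cell.strip())
        if not m:
            raise ValueError(f"unparseable cell {cell!r}")
        out[name] = float(m.group(1))
        if m.group(2) is not None:
            out[f"ci_{name}"] = (float(m.group(2)), float(m.group(3)))
    return out


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI run's outputs."""

    command: str
    config: dict = field(default_factory=dict)
    seed: int | None = None
    input_digests: dict = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        if not self.package_version:
            from cpmkit import __version__

            self.package_version = __version__

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.input_digests[p.name] = _digest(p)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
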