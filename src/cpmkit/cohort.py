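"""Synthetic two-session cohort generator.

Emulates the statistical structure the downstream analyses assume, without
any clinical data: each subject carries a stable feature "fingerprint"
shared by both scanning sessions plus independent session noise, a sparse
set of signal features is linearly related to the post-treatment outcome,
and the outcome itself is a bounded integer severity score (0-25, like a
clinician-rated anxiety scale) influenced by age, sex, and baseline
severity. A latent-factor timecourse generator feeds the connectivity
pipeline when node timecourses rather than ready-made features are wanted.

The generative model for feature e of subject i in session s is

    x[i, s, e] = mu[e] + sigma_subject * S[i, e] + sigma_session * E[i, s, e]

with mu, S, E all standard normal, S drawn once per subject (the
fingerprint) and E independently per session. The post-treatment outcome is

    y_post[i] = intercept + beta_signal * mean(baseline signal features of i)
                + beta_age * age[i] + beta_sex * sex[i]
                + beta_baseline * y_base[i] + Normal(0, sigma_outcome)

rounded to the nearest integer and clipped into ``outcome_range``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from cpmkit.connectome import FeatureMatrix, edge_feature_meta

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "generate_timecourses"]


@dataclass
class CohortSpec:
    """Generative parameters for a synthetic two-session study.

    Feature count is ``n_nodes * (n_nodes - 1) / 2`` edges when ``n_nodes``
    is set, or ``n_vertices`` vertexwise features otherwise. Defaults mirror
    a single-site pediatric treatment cohort: 54 subjects, a 216-node
    parcellation (23,220 edges), ages 8-17, outcome on the 0-25 scale with
    baseline severity centered near 15 and post-treatment scores near 9.
    """

    n_subjects: int = 54
    n_nodes: int | None = 216
    n_vertices: int | None = None
    n_timepoints: int = 300
    sigma_subject: float = 1.0
    sigma_session: float = 1.0
    signal_feature_count: int = 200
    beta_signal: float = 3.0
    beta_age: float = 0.2
    beta_sex: float = 1.0
    beta_baseline: float = 0.5
    sigma_outcome: float = 3.0
    intercept: float = -1.0
    outcome_range: tuple[int, int] = (0, 25)
    baseline_mean: float = 14.6
    baseline_sd: float = 2.8
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.n_nodes is None) == (self.n_vertices is None):
            raise ValueError("specify exactly one of n_nodes or n_vertices")
        for name in ("sigma_subject", "sigma_session", "sigma_outcome"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        for name in ("beta_signal", "beta_age", "beta_sex", "beta_baseline", "intercept"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.signal_feature_count > self.n_features:
            raise ValueError(
                f"signal_feature_count ({self.signal_feature_count}) exceeds "
                f"feature count ({self.n_features})"
            )
        lo, hi = self.outcome_range
        if not lo < hi:
            raise ValueError("outcome_range must satisfy min < max")

    @property
    def n_features(self) -> int:
        if self.n_nodes is not None:
            return self.n_nodes * (self.n_nodes - 1) // 2
        return int(self.n_vertices)

    @property
    def feature_kind(self) -> str:
        return "edge" if self.n_nodes is not None else "vertex"


@dataclass
class SyntheticCohort:
    """A generated cohort: two feature matrices, phenotypes, and the truth."""

    baseline_features: FeatureMatrix
    followup_features: FeatureMatrix
    phenotypes: pd.DataFrame
    truth: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_features.subject_ids != self.followup_features.subject_ids:
            raise ValueError("sessions must share subject order")
        if self.baseline_features.n_features != self.followup_features.n_features:
            raise ValueError("sessions must share feature order")
        idx = np.asarray(self.truth.get("signal_indices", []), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.baseline_features.n_features):
            raise ValueError("truth indices out of feature range")


def _feature_meta(spec: CohortSpec) -> pd.DataFrame:
    if spec.feature_kind == "edge":
        labels = [f"node{i:03d}" for i in range(spec.n_nodes)]
        return edge_feature_meta(labels)
    return pd.DataFrame(
        {
            "feature_id": [f"vtx{i:06d}" for i in range(spec.n_features)],
            "vertex_id": np.arange(spec.n_features),
        }
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a two-session cohort with phenotypes from ``spec``.

    Deterministic for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_subjects, spec.n_features

    mu = rng.standard_normal(m)
    subject_effect = rng.standard_normal((n, m))
    base = mu + spec.sigma_subject * subject_effect + spec.sigma_session * rng.standard_normal((n, m))
    follow = mu + spec.sigma_subject * subject_effect + spec.sigma_session * rng.standard_normal((n, m))

    signal_idx = rng.choice(m, size=spec.signal_feature_count, replace=False)
    signal_idx.sort()

    age = rng.uniform(8.0, 17.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    lo, hi = spec.outcome_range
    y_base = np.clip(
        np.round(rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)), lo, hi
    )
    signal_mean = base[:, signal_idx].mean(axis=1) if signal_idx.size else np.zeros(n)
    y_cont = (
        spec.intercept
        + spec.beta_signal * signal_mean
        + spec.beta_age * age
        + spec.beta_sex * sex
        + spec.beta_baseline * y_base
        + rng.normal(0.0, spec.sigma_outcome, size=n)
    )
    y_post = np.clip(np.round(y_cont), lo, hi)

    # motion summaries resembling a low-motion pediatric sample
    fd_mean = np.abs(rng.normal(0.11, 0.05, size=n))
    fd_pct = np.clip(np.abs(rng.normal(10.0, 9.0, size=n)), 0.0, 100.0)

    subject_ids = [f"sub{i:04d}" for i in range(n)]
    meta = _feature_meta(spec)
    phenotypes = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "outcome_baseline": y_base.astype(int),
            "outcome_post": y_post.astype(int),
            "age": age,
            "sex": sex.astype(int),
            "scanner": ["scannerA"] * n,
            "fd_mean": fd_mean,
            "fd_pct_above": fd_pct,
        }
    )
    truth = {
        "signal_indices": signal_idx.tolist(),
        "coefficients": {
            "intercept": spec.intercept,
            "beta_signal": spec.beta_signal,
            "beta_age": spec.beta_age,
            "beta_sex": spec.beta_sex,
            "beta_baseline": spec.beta_baseline,
            "sigma_outcome": spec.sigma_outcome,
        },
        "spec": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()},
    }
    kind = spec.feature_kind
    return SyntheticCohort(
        FeatureMatrix(base, subject_ids, kind, meta),
        FeatureMatrix(follow, subject_ids, kind, meta),
        phenotypes,
        truth,
    )


def generate_timecourses(
    spec: CohortSpec,
    n_latent: int = 5,
    common_loadings: np.ndarray | None = None,
    noise_sd: float = 1.0,
) -> dict[str, dict[str, np.ndarray]]:
    """Latent-factor node timecourses for each subject and session.

    Node signals are ``F @ L_i.T + noise`` where the time x latent factor
    scores ``F`` are redrawn per subject/session and the node loadings
    ``L_i = L_common + sigma_subject * L_i_subj`` carry the subject-stable
    component, so the population correlation structure contains a
    subject-specific part. Returns
    ``{subject_id: {"baseline": T x N array, "followup": T x N array}}``.
    """
    if spec.n_nodes is None:
        raise ValueError("timecourse simulation requires n_nodes")
    T, N = spec.n_timepoints, spec.n_nodes
    if T < N + 2:
        raise ValueError(
            f"n_timepoints ({T}) must be >= n_nodes + 2 ({N + 2}) so partial "
            "correlation stays estimable"
        )
    rng = np.random.default_rng(spec.seed)
    if common_loadings is None:
        common_loadings = rng.standard_normal((N, n_latent))
    else:
        common_loadings = np.asarray(common_loadings, dtype=float)
        if common_loadings.shape[0] != N:
            raise ValueError("common_loadings must have one row per node")
        n_latent = common_loadings.shape[1]
    out: dict[str, dict[str, np.ndarray]] = {}
    for i in range(spec.n_subjects):
        L = common_loadings + spec.sigma_subject * rng.standard_normal((N, n_latent))
        sessions = {}
        for name in ("baseline", "followup"):
            F = rng.standard_normal((T, n_latent))
            sessions[name] = F @ L.T + noise_sd * rng.standard_normal((T, N))
        out[f"sub{i:04d}"] = sessions
    return out
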