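"""Connectivity features: timecourse residualization, (partial) correlation
matrices with Fisher z, edge vectorization, motion QC, and mesh smoothing.

The feature pipeline mirrors standard resting-state practice: node
timecourses are cleaned by linear confound regression, pairwise association
is measured by Pearson correlation (full) or by the correlation of each pair
after regressing out all remaining nodes (partial), correlations are
variance-stabilized with Fisher's z = arctanh(r), and the strict upper
triangle of the symmetric matrix is unwrapped into an edge feature vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NodeTimecourses",
    "ConnectivityMatrix",
    "FeatureMatrix",
    "MotionSummary",
    "regress_confounds",
    "compute_rsfc",
    "vectorize_upper",
    "edge_feature_meta",
    "qc_exclude",
    "smooth_on_mesh",
]

#: Motion exclusion thresholds: mean framewise displacement in mm, and the
#: percentage of frames exceeding the per-frame FD cutoff.
FD_MEAN_THRESHOLD = 0.25
FD_PCT_THRESHOLD = 50.0

#: Correlations are clipped to +/-(1 - CLIP_EPS) before arctanh so that a
#: numerically perfect correlation maps to a large finite z.
CLIP_EPS = 1e-12


@dataclass
class NodeTimecourses:
    """Per-session node timecourses: a time x node array plus node labels."""

    values: np.ndarray
    node_labels: list[str] | None = None
    network_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("timecourse array must be 2-D (time x node)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("timecourses contain non-finite values")
        n_nodes = self.values.shape[1]
        if self.node_labels is None:
            self.node_labels = [f"node{i:03d}" for i in range(n_nodes)]
        if self.network_labels is None:
            self.network_labels = ["unassigned"] * n_nodes
        if len(self.node_labels) != n_nodes or len(self.network_labels) != n_nodes:
            raise ValueError("label list lengths must equal the node count")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Node x node symmetric matrix of Fisher-z transformed correlations."""

    z: np.ndarray
    method: str = "full"
    gsr_applied: bool = False
    node_labels: list[str] | None = None
    network_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape[1] != n:
            raise ValueError("connectivity matrix must be square")
        off = ~np.eye(n, dtype=bool)
        if not np.all(np.isfinite(self.z[off])):
            raise ValueError("off-diagonal entries must be finite")
        if n and np.max(np.abs(self.z - self.z.T)) > 1e-10:
            raise ValueError("connectivity matrix is not symmetric")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class FeatureMatrix:
    """Subject x feature matrix with per-feature metadata.

    ``feature_kind`` is ``"edge"`` for unwrapped connectivity (feature count
    must be N(N-1)/2 for some node count N) or ``"vertex"`` for surface-based
    anatomical measurements.
    """

    values: np.ndarray
    subject_ids: list[str]
    feature_kind: str = "edge"
    feature_meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (subject x feature)")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length must match row count")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")
        if self.feature_kind not in ("edge", "vertex"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.feature_kind == "edge":
            m = self.values.shape[1]
            n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
            if n * (n - 1) // 2 != m:
                raise ValueError(
                    f"edge feature count {m} is not N(N-1)/2 for any integer N"
                )
        if self.feature_meta is not None and len(self.feature_meta) != self.values.shape[1]:
            raise ValueError("feature_meta length must match feature count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = (
            list(self.feature_meta["feature_id"])
            if self.feature_meta is not None and "feature_id" in self.feature_meta
            else [f"f{i:06d}" for i in range(self.n_features)]
        )
        return pd.DataFrame(self.values, index=pd.Index(self.subject_ids, name="subject_id"), columns=cols)


@dataclass
class MotionSummary:
    """Per-scan head-motion summary used for quality control."""

    fd_mean: float
    fd_pct_above: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.fd_mean) or self.fd_mean < 0:
            raise ValueError("fd_mean must be a finite non-negative number (mm)")
        if not (0.0 <= self.fd_pct_above <= 100.0):
            raise ValueError("fd_pct_above must lie in [0, 100]")


def _rank_check(design: np.ndarray, names: list[str]) -> None:
    """Raise naming the offending columns if ``design`` is rank deficient."""
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return
    bad: list[str] = []
    kept = np.empty((design.shape[0], 0))
    for j in range(design.shape[1]):
        cand = np.column_stack([kept, design[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            bad.append(names[j])
    raise ValueError(f"design is rank deficient; redundant columns: {bad}")


def regress_confounds(
    tc: NodeTimecourses, confounds: np.ndarray | None = None
) -> NodeTimecourses:
    """Replace each node timecourse by its residual after least-squares
    regression on an intercept plus the given confound timecourses.

    With no confounds this reduces to per-node mean removal.
    """
    T = tc.n_timepoints
    if confounds is None or (hasattr(confounds, "size") and np.size(confounds) == 0):
        conf = np.empty((T, 0))
    else:
        conf = np.asarray(confounds, dtype=float)
        if conf.ndim == 1:
            conf = conf[:, None]
        if conf.shape[0] != T:
            raise ValueError(
                f"confound rows ({conf.shape[0]}) must match timepoints ({T})"
            )
    design = np.column_stack([np.ones(T), conf])
    names = ["intercept"] + [f"confound{i}" for i in range(conf.shape[1])]
    _rank_check(design, names)
    beta, *_ = np.linalg.lstsq(design, tc.values, rcond=None)
    resid = tc.values - design @ beta
    return NodeTimecourses(resid, list(tc.node_labels), list(tc.network_labels))


def _full_correlation(x: np.ndarray) -> np.ndarray:
    return np.corrcoef(x, rowvar=False)


def _partial_correlation(x: np.ndarray) -> np.ndarray:
    """Partial correlation of every node pair given all remaining nodes.

    Computed from the precision matrix: pr[a,b] = -P[a,b]/sqrt(P[a,a]P[b,b]),
    which equals the correlation of the residuals of nodes a and b after
    regressing out all other node timecourses (intercept included via the
    covariance). Falls back to the pseudo-inverse when the sample covariance
    is singular.
    """
    cov = np.cov(x, rowvar=False)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(cov)
    d = np.sqrt(np.diag(prec))
    pr = -prec / np.outer(d, d)
    np.fill_diagonal(pr, 1.0)
    return pr


def compute_rsfc(
    tc: NodeTimecourses, method: str = "full", gsr_applied: bool = False
) -> ConnectivityMatrix:
    """Pairwise node association as a Fisher-z connectivity matrix.

    ``method="full"`` computes plain Pearson correlations; ``"partial"``
    computes the correlation of each pair after regressing out every other
    node. Correlations are clipped to +/-(1 - 1e-12) before z = arctanh(r).
    """
    x = tc.values
    T, n = x.shape
    if T < 3:
        raise ValueError("at least 3 timepoints required")
    spread = np.ptp(x, axis=0)
    if np.any(spread == 0):
        bad = [tc.node_labels[i] for i in np.flatnonzero(spread == 0)]
        raise ValueError(f"constant timecourse for node(s): {bad}")
    if method == "full":
        r = _full_correlation(x)
    elif method == "partial":
        if T <= n + 1:
            raise ValueError(
                f"partial correlation needs timepoints > nodes + 1 (got T={T}, N={n})"
            )
        r = _partial_correlation(x)
    else:
        raise ValueError(f"unknown method {method!r}")
    r = np.clip(r, -(1 - CLIP_EPS), 1 - CLIP_EPS)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        z,
        method=method,
        gsr_applied=gsr_applied,
        node_labels=list(tc.node_labels),
        network_labels=list(tc.network_labels),
    )


def edge_feature_meta(
    node_labels: list[str], network_labels: list[str] | None = None
) -> pd.DataFrame:
    """Metadata table for row-major strict-upper-triangle edge ordering."""
    n = len(node_labels)
    if network_labels is None:
        network_labels = ["unassigned"] * n
    ia, ib = np.triu_indices(n, k=1)
    return pd.DataFrame(
        {
            "feature_id": [f"edge{k:06d}" for k in range(len(ia))],
            "node_a": [node_labels[a] for a in ia],
            "node_b": [node_labels[b] for b in ib],
            "network_a": [network_labels[a] for a in ia],
            "network_b": [network_labels[b] for b in ib],
        }
    )


def vectorize_upper(cm: ConnectivityMatrix) -> tuple[np.ndarray, pd.DataFrame]:
    """Unwrap the strict upper triangle (row-major) into an edge vector.

    For N nodes the vector has length N(N-1)/2; the accompanying metadata
    records edge endpoints and their network assignments.
    """
    z = cm.z
    if z.size and np.max(np.abs(z - z.T)) > 1e-10:
        raise ValueError("matrix asymmetric beyond 1e-10; refusing to vectorize")
    ia, ib = np.triu_indices(cm.n_nodes, k=1)
    vec = z[ia, ib]
    meta = edge_feature_meta(list(cm.node_labels or []), cm.network_labels)
    if cm.node_labels is None:
        meta = edge_feature_meta([f"node{i:03d}" for i in range(cm.n_nodes)])
    return vec, meta


def qc_exclude(ms: MotionSummary) -> bool:
    """True if the scan fails motion QC.

    Exclusion rule: mean FD strictly greater than 0.25 mm, or strictly more
    than 50% of frames with FD above 0.25 mm. Boundary values are kept.
    """
    return ms.fd_mean > FD_MEAN_THRESHOLD or ms.fd_pct_above > FD_PCT_THRESHOLD


def smoothing_iterations(fwhm: float, edge_len: float) -> int:
    """Iteration count for neighbor-averaging smoothing at a requested FWHM.

    Uses the diffusion approximation FWHM ~= edge_len * sqrt(8 ln2 * k / 3)
    for k averaging iterations on a mesh with typical edge length
    ``edge_len``; solved for k and rounded to the nearest integer >= 1.
    """
    if fwhm <= 0:
        return 0
    k = 3.0 * fwhm**2 / (8.0 * np.log(2.0) * edge_len**2)
    return max(1, int(round(k)))


def smooth_on_mesh(
    values: np.ndarray,
    adjacency: list[list[int]],
    fwhm: float,
    edge_len: float = 1.0,
) -> np.ndarray:
    """Smooth per-vertex values by iterated neighbor averaging.

    Each iteration replaces a vertex value by the mean of itself and its
    neighbors; the iteration count is calibrated to the requested FWHM (see
    :func:`smoothing_iterations`). The global mean is preserved exactly by
    re-centering after smoothing. Isolated vertices are left unchanged with
    a warning. ``fwhm=0`` returns the input unchanged.
    """
    v = np.asarray(values, dtype=float).copy()
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return v
    n = v.size
    for i, nbrs in enumerate(adjacency):
        for j in nbrs:
            if i not in adjacency[j]:
                raise ValueError(f"adjacency not symmetric at ({i}, {j})")
    isolated = [i for i, nbrs in enumerate(adjacency) if len(nbrs) == 0]
    if isolated:
        warnings.warn(
            f"{len(isolated)} isolated vertex(es) left unchanged by smoothing",
            stacklevel=2,
        )
    mean0 = v.mean()
    k = smoothing_iterations(fwhm, edge_len)
    deg = np.array([len(nbrs) for nbrs in adjacency], dtype=float)
    for _ in range(k):
        acc = v.copy()
        for i, nbrs in enumerate(adjacency):
            if nbrs:
                acc[i] += v[list(nbrs)].sum()
        v = acc / (deg + 1.0)
    # neighbor averaging on an irregular mesh drifts the mean; restore it by
    # shifting the connected vertices uniformly (isolated ones stay untouched)
    connected = np.array([len(nbrs) > 0 for nbrs in adjacency])
    if connected.any():
        v[connected] += (mean0 * n - v.sum()) / connected.sum()
    return v
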