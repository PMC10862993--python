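"""Connectome fingerprinting: subject identification and edgewise statistics.

Identification matches every subject's baseline feature vector to the most
correlated follow-up vector (with replacement); the number of correct
matches k out of n subjects is tested against chance with the upper tail of
a Binomial(n, 1/n) distribution, evaluated in log space so p-values far
below double-precision rounding of individual terms remain accurate.

Because a Pearson correlation is the dot product of mean-centered,
unit-norm vectors, the cross-session similarity decomposes per feature:

    r_ij = sum_e phi_ij(e),    phi_ij(e) = xb_i(e) * xf_j(e)

where xb_i / xf_j are the normalized baseline/follow-up vectors. A feature
helps identify subject i when its self-match contribution phi_ii(e) exceeds
the cross-subject contributions. The chance probability of that is
estimated by the rank of phi_ii(e) within its row and column:

    P_i(e) = [ sum_j I(phi_ij(e) >= phi_ii(e))
             + sum_j I(phi_ji(e) >= phi_ii(e)) - 1 ] / (2n - 1)

bounded in [1/(2n-1), 1]. Fisher-combining over subjects gives the
differential power DP(e) = -2 sum_i ln P_i(e), which under the null of
uninformative features is approximately chi-squared with 2n degrees of
freedom, yielding a per-feature p-value and a principled edge-selection
rule (e.g., to feed the predictive model's ``dp`` selection mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from cpmkit.connectome import FeatureMatrix

__all__ = [
    "FingerprintResult",
    "normalize_features",
    "identify",
    "binomial_p",
    "phi_contributions",
    "p_hat_matrix",
    "differential_power",
    "dp_select",
    "fingerprint",
]

logger = logging.getLogger(__name__)


@dataclass
class FingerprintResult:
    """Identification outcome and (optionally) per-feature statistics."""

    similarity: np.ndarray
    matches_fwd: np.ndarray
    matches_rev: np.ndarray
    k_fwd: int
    k_rev: int
    p_fwd: float
    p_rev: float
    n: int
    p_hat: np.ndarray | None = field(default=None, repr=False)
    dp: np.ndarray | None = field(default=None, repr=False)
    dp_p: np.ndarray | None = field(default=None, repr=False)

    @property
    def accuracy_fwd(self) -> float:
        return self.k_fwd / self.n

    @property
    def accuracy_rev(self) -> float:
        return self.k_rev / self.n

    def report(self) -> dict:
        return {
            "n": self.n,
            "k_fwd": self.k_fwd,
            "k_rev": self.k_rev,
            "accuracy_fwd": self.accuracy_fwd,
            "accuracy_rev": self.accuracy_rev,
            "p_fwd": self.p_fwd,
            "p_rev": self.p_rev,
        }


def _values(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a subject x feature matrix")
    return x


def normalize_features(x) -> np.ndarray:
    """Center each row and scale it to unit norm.

    After normalization the dot product of any two rows equals the Pearson
    correlation of the original rows.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1, keepdims=True)
    if np.any(norms == 0):
        bad = np.flatnonzero(norms.ravel() == 0).tolist()
        raise ValueError(f"constant feature vector for row(s) {bad}")
    return xc / norms


def binomial_p(k: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n, 1/n), computed in log space.

    This is the chance probability of at least k correct identifications
    when each of n subjects is matched with replacement.
    """
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, {n}]")
    ks = np.arange(k, n + 1)
    return float(np.exp(logsumexp(stats.binom.logpmf(ks, n, 1.0 / n))))


def identify(baseline, followup) -> FingerprintResult:
    """Match subjects across sessions by maximal feature-vector correlation.

    similarity[i, j] is the Pearson correlation of subject i's baseline
    vector with subject j's follow-up vector. The forward match for i is
    argmax_j similarity[i, j]; the reverse match for j is argmax_i. Matching
    is with replacement, so the Binomial(n, 1/n) tail gives the p-value for
    the number of correct matches. Ties (probability zero on real-valued
    data) break toward the lowest index with a warning.
    """
    xb = _values(baseline)
    xf = _values(followup)
    if xb.shape != xf.shape:
        raise ValueError("baseline and follow-up must have identical shape")
    n = xb.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if (
        isinstance(baseline, FeatureMatrix)
        and isinstance(followup, FeatureMatrix)
        and baseline.subject_ids != followup.subject_ids
    ):
        raise ValueError("sessions must list the same subjects in the same order")
    nb = normalize_features(xb)
    nf = normalize_features(xf)
    sim = nb @ nf.T
    row_max_ties = np.sum(sim == sim.max(axis=1, keepdims=True), axis=1)
    col_max_ties = np.sum(sim == sim.max(axis=0, keepdims=True), axis=0)
    if np.any(row_max_ties > 1) or np.any(col_max_ties > 1):
        logger.warning("similarity argmax tie; breaking toward the lowest index")
    matches_fwd = sim.argmax(axis=1)
    matches_rev = sim.argmax(axis=0)
    k_fwd = int(np.sum(matches_fwd == np.arange(n)))
    k_rev = int(np.sum(matches_rev == np.arange(n)))
    return FingerprintResult(
        similarity=sim,
        matches_fwd=matches_fwd,
        matches_rev=matches_rev,
        k_fwd=k_fwd,
        k_rev=k_rev,
        p_fwd=binomial_p(k_fwd, n),
        p_rev=binomial_p(k_rev, n),
        n=n,
    )


def phi_contributions(xb_norm, xf_norm) -> np.ndarray:
    """Per-feature contributions phi(e) = xb(e) * xf(e) for one vector pair.

    Inputs must already be normalized (zero mean, unit norm); the sum of
    the contributions equals the Pearson correlation of the raw vectors.
    """
    xb_norm = np.asarray(xb_norm, dtype=float).ravel()
    xf_norm = np.asarray(xf_norm, dtype=float).ravel()
    if xb_norm.size != xf_norm.size:
        raise ValueError("vectors must have equal length")
    for name, v in (("baseline", xb_norm), ("followup", xf_norm)):
        if abs(v.sum()) > 1e-8 or abs(v @ v - 1.0) > 1e-8:
            raise ValueError(
                f"{name} vector is not normalized (use normalize_features first)"
            )
    return xb_norm * xf_norm


def p_hat_matrix(baseline, followup, block_size: int = 512) -> np.ndarray:
    """Per-(subject, feature) match-contribution probabilities.

    For each feature e, phi[i, j] = xb_i(e) * xf_j(e) over all subject
    pairs; P_i(e) is the rank of the self term phi[i, i] within its row and
    column, divided by 2n - 1 (both sums count the self term once; the -1
    removes the duplicate). Values lie in [1/(2n-1), 1]: low values flag
    features whose self-match contribution is rarely exceeded by chance.

    The n x n x features tensor is processed in feature blocks so the
    working set stays bounded; results are independent of ``block_size``.
    """
    nb = normalize_features(_values(baseline))
    nf = normalize_features(_values(followup))
    if nb.shape != nf.shape:
        raise ValueError("baseline and follow-up must have identical shape")
    n, m = nb.shape
    out = np.empty((n, m))
    for start in range(0, m, block_size):
        sl = slice(start, min(start + block_size, m))
        # phi has shape (n_baseline, n_followup, block)
        phi = nb[:, None, sl] * nf[None, :, sl]
        diag = phi[np.arange(n), np.arange(n), :]          # (n, block)
        ge_row = (phi >= diag[:, None, :]).sum(axis=1)     # sum over j of phi_ij >= phi_ii
        ge_col = (phi >= diag[None, :, :]).sum(axis=0)     # sum over j of phi_ji >= phi_ii
        out[:, sl] = (ge_row + ge_col - 1) / (2 * n - 1)
    return out


def differential_power(p_hat: np.ndarray, n: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """DP(e) = -2 sum_i ln P_i(e) with its chi-squared(2n) upper-tail p.

    Under the null that feature e carries no subject-specific information,
    each -2 ln P_i(e) is approximately chi-squared with 2 degrees of
    freedom, so their sum over the n subjects is chi-squared with 2n.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    if p_hat.ndim == 1:
        p_hat = p_hat[:, None]
    if np.any(p_hat <= 0) or np.any(p_hat > 1):
        raise ValueError("all match probabilities must lie in (0, 1]")
    n = n if n is not None else p_hat.shape[0]
    dp = -2.0 * np.log(p_hat).sum(axis=0)
    p = stats.chi2.sf(dp, df=2 * n)
    return dp.ravel(), p.ravel()


def dp_select(dp_p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of features whose DP p-value falls below ``alpha``.

    The mask plugs into the predictive model's ``dp`` selection mode, so
    the most subject-identifying features can be used as predictors.
    """
    dp_p = np.asarray(dp_p, dtype=float)
    if np.any(dp_p < 0) or np.any(dp_p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return dp_p < alpha


def fingerprint(baseline, followup, block_size: int = 512) -> FingerprintResult:
    """Full fingerprinting analysis: identification plus DP statistics."""
    result = identify(baseline, followup)
    result.p_hat = p_hat_matrix(baseline, followup, block_size=block_size)
    result.dp, result.dp_p = differential_power(result.p_hat, n=result.n)
    return result
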