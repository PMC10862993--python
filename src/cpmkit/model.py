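"""Two-stage predictive modeling core (CPM and its anatomical analogue).

Stage one screens every feature (connectivity edge or surface vertex) for
association with the outcome at a p-value threshold (default 0.01), keeping
positively and negatively associated features in separate masks. Stage two
sums each subject's selected feature values into one (or two) network
summary scores and regresses the outcome on them by ordinary least squares,
optionally together with covariates. Covariates can be ignored, entered as
predictors of interest, or treated as nuisance: in the nuisance scheme
their effects are estimated on the training set, outcome and summaries are
residualized before the stage-two fit, held-out data are residualized with
coefficients from the training set (leave-one-out) or from the test set
itself (external validation), and the nuisance-predicted component is added
back so predictions stay on the original outcome scale.

Evaluation is by leave-one-out cross-validation — feature selection and all
fitting redone inside every fold — or by a single fit applied to an
external cohort. Per-fold selection masks are retained so the features that
recur across folds can be tabulated.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from cpmkit.connectome import FeatureMatrix

__all__ = [
    "ModelConfig",
    "SelectionResult",
    "TrainedModel",
    "PredictionResult",
    "first_stage_select",
    "summarize_features",
    "fit_second_stage",
    "predict",
    "loocv",
    "external_validate",
    "feature_frequency",
    "motion_check",
]

logger = logging.getLogger(__name__)

VALID_MODES = ("positive", "negative", "both", "dp")
VALID_ROLES = ("none", "predictors", "nuisance")
VALID_COVARIATES = ("age", "sex", "scanner", "outcome_baseline")


@dataclass
class ModelConfig:
    """Configuration of one model variant.

    selection_mode
        Which stage-one features feed stage two: positively associated,
        negatively associated, both (two summary columns), or a
        fingerprint-derived differential-power mask (``dp``).
    covariate_role
        ``none`` (ignore covariates), ``predictors`` (enter them in both
        stages as regressors of interest), or ``nuisance`` (residualize).
    outcome_def
        ``post`` predicts the post-treatment score; ``change`` predicts
        post minus baseline (negative = improvement).
    weighting
        ``r_weighted`` multiplies each selected feature by its training-set
        correlation with the outcome before summing; default is a plain sum.
    """

    selection_mode: str = "positive"
    alpha_select: float = 0.01
    covariate_role: str = "none"
    covariates: tuple[str, ...] = ()
    outcome_def: str = "post"
    weighting: str = "none"
    dp_alpha: float = 0.05
    dp_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.selection_mode not in VALID_MODES:
            raise ValueError(f"selection_mode must be one of {VALID_MODES}")
        if self.covariate_role not in VALID_ROLES:
            raise ValueError(f"covariate_role must be one of {VALID_ROLES}")
        if not 0.0 <= self.alpha_select <= 1.0:
            raise ValueError("alpha_select must lie in [0, 1]")
        if self.outcome_def not in ("post", "change"):
            raise ValueError("outcome_def must be 'post' or 'change'")
        if self.weighting not in ("none", "r_weighted"):
            raise ValueError("weighting must be 'none' or 'r_weighted'")
        bad = set(self.covariates) - set(VALID_COVARIATES)
        if bad:
            raise ValueError(f"unknown covariates {sorted(bad)}")
        if self.selection_mode == "dp" and self.dp_mask is None:
            raise ValueError(
                "selection_mode='dp' requires a dp_mask from a fingerprinting run"
            )


@dataclass
class SelectionResult:
    """Stage-one screening output: per-feature association and sign masks."""

    r: np.ndarray
    p: np.ndarray
    positive_mask: np.ndarray
    negative_mask: np.ndarray

    @property
    def n_positive(self) -> int:
        return int(self.positive_mask.sum())

    @property
    def n_negative(self) -> int:
        return int(self.negative_mask.sum())


@dataclass
class TrainedModel:
    """A fitted stage-two model plus everything needed to predict new data."""

    selection: SelectionResult
    config: ModelConfig
    beta: np.ndarray                       # intercept, summary slope(s), covariate slopes
    summary_names: list[str]
    covariate_names: list[str]
    nuisance_coefs: dict | None = None     # {"gamma_y": ..., "gamma_s": ...} (train set)
    fallback: bool = False                 # empty selection -> covariate/intercept-only
    n_features: int = 0


@dataclass
class PredictionResult:
    """Observed/predicted outcomes with per-fold provenance."""

    y: np.ndarray
    yhat: np.ndarray
    subject_ids: list[str]
    fold: np.ndarray | None = None
    fold_positive_masks: np.ndarray | None = field(default=None, repr=False)
    fold_negative_masks: np.ndarray | None = field(default=None, repr=False)
    fallback_folds: list[int] = field(default_factory=list)
    feature_meta: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# helpers

def _as_values(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    return np.asarray(features, dtype=float)


def _residualize(x: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares residuals of ``x`` (n or n x k) on ``design``; returns
    (residuals, coefficients)."""
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta, beta


def _design_rank_check(design: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad: list[str] = []
        kept = np.empty((design.shape[0], 0))
        for j, name in enumerate(names):
            cand = np.column_stack([kept, design[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(name)
        raise ValueError(f"rank-deficient design; redundant columns: {bad}")


def build_covariate_matrix(
    phenotypes: pd.DataFrame, covariates: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Assemble the covariate design from a phenotype table.

    ``scanner`` is dummy-coded (first level dropped); the rest are numeric.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov == "scanner":
            dummies = pd.get_dummies(phenotypes["scanner"], drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(f"scanner[{c}]")
        else:
            cols.append(phenotypes[cov].to_numpy(dtype=float))
            names.append(cov)
    if not cols:
        return np.empty((len(phenotypes), 0)), []
    return np.column_stack(cols), names


def outcome_vector(phenotypes: pd.DataFrame, outcome_def: str) -> np.ndarray:
    y = phenotypes["outcome_post"].to_numpy(dtype=float)
    if outcome_def == "change":
        y = y - phenotypes["outcome_baseline"].to_numpy(dtype=float)
    return y


# ---------------------------------------------------------------------------
# stage one

def first_stage_select(
    features,
    outcome,
    covariates: np.ndarray | None = None,
    config: ModelConfig | None = None,
) -> SelectionResult:
    """Screen every feature for association with the outcome.

    Without covariates: Pearson correlation of each feature with the
    outcome, with the two-sided parametric p-value from the t transform
    t = r sqrt(df / (1 - r^2)), df = n - 2. With covariates: partial
    correlation of feature and outcome given the covariates (both
    residualized on [intercept, covariates]; df = n - 2 - k). A feature is
    selected when p < alpha and its association sign matches the mask.
    """
    config = config or ModelConfig()
    x = _as_values(features)
    y = np.asarray(outcome, dtype=float).ravel()
    n = y.size
    if x.shape[0] != n:
        raise ValueError("feature rows must match outcome length")
    if n < 4:
        raise ValueError("need at least 4 subjects for feature screening")
    if np.std(y) == 0:
        raise ValueError("constant outcome: associations undefined")
    if covariates is None or covariates.size == 0:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    k = cov.shape[1]
    if k >= n - 2:
        raise ValueError(f"too many covariates (k={k}) for n={n}")
    if k:
        design = np.column_stack([np.ones(n), cov])
        xr, _ = _residualize(x, design)
        yr, _ = _residualize(y, design)
    else:
        xr = x - x.mean(axis=0)
        yr = y - y.mean()
    xs = np.sqrt(np.sum(xr * xr, axis=0))
    ys = math.sqrt(float(np.sum(yr * yr)))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xr.T @ yr) / (xs * ys)
    r = np.where(xs == 0, 0.0, r)          # constant features associate with nothing
    r = np.clip(r, -1.0, 1.0)
    df = n - 2 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    sig = p < config.alpha_select
    return SelectionResult(
        r=r, p=p, positive_mask=sig & (r > 0), negative_mask=sig & (r < 0)
    )


# ---------------------------------------------------------------------------
# stage two

def summarize_features(
    features, selection: SelectionResult, config: ModelConfig
) -> tuple[np.ndarray, list[str], bool]:
    """Collapse selected features into per-subject summary predictors.

    Returns ``(summaries, names, fallback)``; ``fallback`` is True when the
    relevant mask(s) are empty, in which case stage two degrades to a
    covariate-only (or intercept-only) model and a warning is logged.
    """
    x = _as_values(features)
    weights = selection.r if config.weighting == "r_weighted" else np.ones_like(selection.r)

    def masked_sum(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            return np.zeros(x.shape[0])
        return x[:, mask] @ weights[mask]

    mode = config.selection_mode
    if mode == "positive":
        cols, names = [masked_sum(selection.positive_mask)], ["sum_positive"]
        fallback = selection.n_positive == 0
    elif mode == "negative":
        cols, names = [masked_sum(selection.negative_mask)], ["sum_negative"]
        fallback = selection.n_negative == 0
    elif mode == "both":
        cols = [masked_sum(selection.positive_mask), masked_sum(selection.negative_mask)]
        names = ["sum_positive", "sum_negative"]
        if selection.n_positive == 0 or selection.n_negative == 0:
            logger.warning(
                "both-mode with an empty mask (pos=%d, neg=%d); empty column is all zeros",
                selection.n_positive, selection.n_negative,
            )
        fallback = selection.n_positive == 0 and selection.n_negative == 0
    elif mode == "dp":
        if config.dp_mask is None:
            raise ValueError("dp mode requires config.dp_mask")
        mask = np.asarray(config.dp_mask, dtype=bool)
        if mask.size != x.shape[1]:
            raise ValueError("dp_mask length must match feature count")
        cols, names = [masked_sum(mask)], ["sum_dp"]
        fallback = not mask.any()
    else:  # pragma: no cover - guarded by ModelConfig
        raise ValueError(mode)
    if fallback:
        logger.warning("empty feature selection; falling back to covariate-only model")
    return np.column_stack(cols), names, fallback


def fit_second_stage(
    summaries: np.ndarray,
    outcome,
    covariates: np.ndarray | None = None,
    config: ModelConfig | None = None,
    selection: SelectionResult | None = None,
    summary_names: list[str] | None = None,
    covariate_names: list[str] | None = None,
    fallback: bool = False,
) -> TrainedModel:
    """Ordinary least squares of the outcome on the summary predictor(s).

    covariate_role='predictors': OLS on [intercept, summaries, covariates].
    covariate_role='nuisance': nuisance coefficients are estimated on the
    training data, outcome and summaries are residualized, and OLS is run
    on the residuals; both coefficient sets are stored.
    covariate_role='none': OLS on [intercept, summaries].
    """
    config = config or ModelConfig()
    y = np.asarray(outcome, dtype=float).ravel()
    s = np.asarray(summaries, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    n = y.size
    if covariates is None:
        covariates = np.empty((n, 0))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    summary_names = summary_names or [f"summary{i}" for i in range(s.shape[1])]
    covariate_names = covariate_names or [f"covariate{i}" for i in range(cov.shape[1])]
    if fallback:
        s = np.empty((n, 0))
        summary_names = []

    role = config.covariate_role if cov.shape[1] else "none"
    nuisance_coefs = None
    if role == "nuisance":
        z = np.column_stack([np.ones(n), cov])
        _design_rank_check(z, ["intercept"] + covariate_names)
        y_res, gamma_y = _residualize(y, z)
        s_res, gamma_s = _residualize(s, z)
        design = np.column_stack([np.ones(n), s_res])
        _design_rank_check(design, ["intercept"] + summary_names)
        beta, *_ = np.linalg.lstsq(design, y_res, rcond=None)
        nuisance_coefs = {"gamma_y": gamma_y, "gamma_s": gamma_s}
    else:
        parts = [np.ones((n, 1)), s]
        names = ["intercept"] + summary_names
        if role == "predictors":
            parts.append(cov)
            names += covariate_names
        design = np.column_stack(parts)
        _design_rank_check(design, names)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return TrainedModel(
        selection=selection
        if selection is not None
        else SelectionResult(np.zeros(0), np.ones(0), np.zeros(0, bool), np.zeros(0, bool)),
        config=config,
        beta=beta,
        summary_names=summary_names,
        covariate_names=covariate_names,
        nuisance_coefs=nuisance_coefs,
        fallback=fallback,
        n_features=int(s.shape[1]),
    )


def predict(
    model: TrainedModel,
    features,
    covariates: np.ndarray | None = None,
    nuisance_source: str = "train",
) -> np.ndarray:
    """Predict outcomes for new subjects with a trained model.

    Summaries are always computed with the training-set masks (and training
    correlations, if weighted). Under the nuisance scheme the test summaries
    are residualized using nuisance coefficients from the training set
    (``nuisance_source='train'``) or re-estimated on the test set itself
    (``'test'``; requires several test subjects), and the nuisance-predicted
    outcome component is added back so predictions are on the original scale.
    """
    x = _as_values(features)
    if model.selection.r.size and x.shape[1] != model.selection.r.size:
        raise ValueError(
            f"feature count mismatch: model has {model.selection.r.size}, "
            f"input has {x.shape[1]}"
        )
    n = x.shape[0]
    if model.fallback:
        s = np.empty((n, 0))
    else:
        s, _, _ = summarize_features(x, model.selection, model.config)
    if covariates is None:
        covariates = np.empty((n, 0))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]

    role = model.config.covariate_role if cov.shape[1] else "none"
    if role == "nuisance":
        if nuisance_source not in ("train", "test"):
            raise ValueError("nuisance_source must be 'train' or 'test'")
        z = np.column_stack([np.ones(n), cov])
        if nuisance_source == "train":
            if model.nuisance_coefs is None:
                raise ValueError("model has no stored nuisance coefficients")
            gamma_y = model.nuisance_coefs["gamma_y"]
            gamma_s = model.nuisance_coefs["gamma_s"]
        else:
            if n < 2:
                raise ValueError(
                    "nuisance_source='test' needs multiple test subjects; "
                    "use nuisance_source='train' for single-subject folds"
                )
            gamma_s = np.linalg.lstsq(z, s, rcond=None)[0]
            gamma_y = model.nuisance_coefs["gamma_y"]
            # outcome nuisance effects from the test set require observed
            # test outcomes; the add-back uses the train-estimated gamma_y
            # while the summaries are residualized with test-set coefficients
        s_res = s - z @ gamma_s
        design = np.column_stack([np.ones(n), s_res])
        yhat_res = design @ model.beta
        return yhat_res + z @ gamma_y
    parts = [np.ones((n, 1)), s]
    if role == "predictors":
        parts.append(cov)
    design = np.column_stack(parts)
    if design.shape[1] != model.beta.size:
        raise ValueError("design width does not match stored coefficients")
    return design @ model.beta


# ---------------------------------------------------------------------------
# validation drivers

def _train_one(
    x: np.ndarray,
    y: np.ndarray,
    cov: np.ndarray,
    config: ModelConfig,
    summary_names_hint: list[str] | None = None,
    covariate_names: list[str] | None = None,
) -> TrainedModel:
    cov_for_selection = cov if (config.covariate_role != "none" and cov.size) else None
    selection = first_stage_select(x, y, cov_for_selection, config)
    summaries, names, fallback = summarize_features(x, selection, config)
    return fit_second_stage(
        summaries,
        y,
        cov,
        config,
        selection=selection,
        summary_names=names,
        covariate_names=covariate_names,
        fallback=fallback,
    )


def loocv(
    features,
    phenotypes: pd.DataFrame,
    config: ModelConfig | None = None,
) -> PredictionResult:
    """Leave-one-out cross-validation of the full two-stage pipeline.

    Every fold reruns feature selection, summarization, and the stage-two
    fit on the n-1 training subjects, then predicts the held-out subject
    (nuisance coefficients, if any, come from the training set). Per-fold
    selection masks are stored for feature-frequency tables.
    """
    config = config or ModelConfig()
    x = _as_values(features)
    n, m = x.shape
    if n < 4:
        raise ValueError("leave-one-out needs at least 4 subjects")
    if n < 10:
        warnings.warn(f"n={n} is very small for cross-validation", stacklevel=2)
    y = outcome_vector(phenotypes, config.outcome_def)
    cov, cov_names = build_covariate_matrix(phenotypes, config.covariates)
    subject_ids = list(phenotypes["subject_id"]) if "subject_id" in phenotypes else [
        f"sub{i:04d}" for i in range(n)
    ]
    yhat = np.empty(n)
    pos_masks = np.zeros((n, m), dtype=bool)
    neg_masks = np.zeros((n, m), dtype=bool)
    fallback_folds: list[int] = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        model = _train_one(x[tr], y[tr], cov[tr], config, covariate_names=cov_names)
        yhat[i] = predict(model, x[i : i + 1], cov[i : i + 1], nuisance_source="train")[0]
        pos_masks[i] = model.selection.positive_mask
        neg_masks[i] = model.selection.negative_mask
        if model.fallback:
            fallback_folds.append(i)
    meta = features.feature_meta if isinstance(features, FeatureMatrix) else None
    return PredictionResult(
        y=y,
        yhat=yhat,
        subject_ids=subject_ids,
        fold=np.arange(n),
        fold_positive_masks=pos_masks,
        fold_negative_masks=neg_masks,
        fallback_folds=fallback_folds,
        feature_meta=meta,
    )


def external_validate(
    train_features,
    train_phenotypes: pd.DataFrame,
    test_features,
    test_phenotypes: pd.DataFrame,
    config: ModelConfig | None = None,
) -> PredictionResult:
    """Fit once on the training cohort, predict every test-cohort subject.

    Under the nuisance scheme the test set is residualized with nuisance
    coefficients estimated from the test set itself (covariate-shift
    protection available because the test set has many subjects).
    """
    config = config or ModelConfig()
    xtr = _as_values(train_features)
    xte = _as_values(test_features)
    if xtr.shape[1] != xte.shape[1]:
        raise ValueError(
            f"feature count mismatch: train {xtr.shape[1]} vs test {xte.shape[1]}"
        )
    ytr = outcome_vector(train_phenotypes, config.outcome_def)
    yte = outcome_vector(test_phenotypes, config.outcome_def)
    ctr, cov_names = build_covariate_matrix(train_phenotypes, config.covariates)
    cte, _ = build_covariate_matrix(test_phenotypes, config.covariates)
    model = _train_one(xtr, ytr, ctr, config, covariate_names=cov_names)
    yhat = predict(model, xte, cte, nuisance_source="test" if ctr.size else "train")
    subject_ids = list(test_phenotypes["subject_id"]) if "subject_id" in test_phenotypes else [
        f"sub{i:04d}" for i in range(len(yte))
    ]
    meta = (
        train_features.feature_meta
        if isinstance(train_features, FeatureMatrix)
        else None
    )
    return PredictionResult(y=yte, yhat=yhat, subject_ids=subject_ids, feature_meta=meta)


def feature_frequency(
    result: PredictionResult,
    min_frac: float = 0.5,
    feature_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tabulate features selected in at least ``min_frac`` of LOOCV folds.

    Fractions are computed separately for positive and negative masks; the
    returned table has one row per (feature, sign) passing the threshold.
    """
    if result.fold_positive_masks is None:
        raise ValueError("feature frequencies require a LOOCV result with stored masks")
    meta = feature_meta if feature_meta is not None else result.feature_meta
    n_folds = result.fold_positive_masks.shape[0]
    rows = []
    for sign, masks in (
        ("positive", result.fold_positive_masks),
        ("negative", result.fold_negative_masks),
    ):
        frac = masks.sum(axis=0) / n_folds
        for idx in np.flatnonzero(frac >= min_frac):
            row = {"feature_index": int(idx), "sign": sign, "fraction": float(frac[idx])}
            if meta is not None:
                row.update(meta.iloc[idx].to_dict())
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(
            ["sign", "fraction", "feature_index"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return table


def motion_check(
    fd_mean,
    outcome,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> tuple[float, float]:
    """Permutation test that head motion does not predict the outcome.

    Returns ``(r_obs, p)`` where p is the two-tailed probability of a
    permuted |correlation| at least as large as the observed one. By
    default permutations are Monte-Carlo with the identity permutation
    included, p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1); with
    ``exhaustive=True`` (or whenever n! <= n_perm) all n! permutations are
    enumerated and p is an exact proportion.
    """
    fd = np.asarray(fd_mean, dtype=float).ravel()
    y = np.asarray(outcome, dtype=float).ravel()
    n = fd.size
    if n < 5:
        raise ValueError("need at least 5 subjects for the motion check")
    if fd.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    r_obs = float(np.corrcoef(fd, y)[0, 1])
    tol = 1e-12
    # correlation of fd with a permuted y reduces to a dot product of the
    # standardized vectors, so permutations can be evaluated in bulk
    fd_s = (fd - fd.mean()) / (fd.std() * np.sqrt(n))
    y_s = (y - y.mean()) / (y.std() * np.sqrt(n))
    if exhaustive is None:
        exhaustive = math.factorial(n) <= n_perm
    if exhaustive:
        if math.factorial(n) > 5_000_000:
            raise ValueError("exhaustive enumeration infeasible for this n")
        perms = np.array(list(itertools.permutations(range(n))))
        r_perm = y_s[perms] @ fd_s
        return r_obs, float(np.mean(np.abs(r_perm) >= abs(r_obs) - tol))
    rng = np.random.default_rng(seed)
    count = 1  # identity permutation
    chunk = 20_000
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        y_perm = rng.permuted(np.tile(y_s, (b, 1)), axis=1)
        r_perm = y_perm @ fd_s
        count += int(np.sum(np.abs(r_perm) >= abs(r_obs) - tol))
        done += b
    return r_obs, count / (n_perm + 1)
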