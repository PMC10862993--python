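import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpmkit import (
    ModelConfig,
    cv_r2,
    external_validate,
    feature_frequency,
    first_stage_select,
    fit_second_stage,
    generate_cohort,
    loocv,
    motion_check,
    pearson_r,
    predict,
    summarize_features,
)
from cpmkit.model import SelectionResult, outcome_vector
from conftest import null_spec, signal_spec


def make_selection(r, pos=None, neg=None):
    r = np.asarray(r, dtype=float)
    pos = np.zeros(r.size, bool) if pos is None else np.asarray(pos, bool)
    neg = np.zeros(r.size, bool) if neg is None else np.asarray(neg, bool)
    return SelectionResult(r=r, p=np.zeros(r.size), positive_mask=pos, negative_mask=neg)


class TestFirstStageSelect:
    def test_feature_equal_to_outcome_selected(self, rng):
        y = rng.standard_normal(20)
        x = np.column_stack([y, rng.standard_normal((20, 3))])
        sel = first_stage_select(x, y)
        assert sel.positive_mask[0]
        assert sel.p[0] < 1e-12

    def test_alpha_one_selects_every_nonconstant_feature(self, rng):
        x = rng.standard_normal((15, 8))
        y = rng.standard_normal(15)
        sel = first_stage_select(x, y, config=ModelConfig(alpha_select=1.0))
        np.testing.assert_array_equal(sel.positive_mask | sel.negative_mask, np.ones(8, bool))
        np.testing.assert_array_equal(sel.positive_mask, sel.r > 0)

    def test_matches_correlation_test_oracle(self):
        # 10 subjects, 5 features: oracle is scipy's exact correlation test
        rng = np.random.default_rng(99)
        x = rng.standard_normal((10, 5))
        y = rng.standard_normal(10)
        sel = first_stage_select(x, y)
        for e in range(5):
            res = stats.pearsonr(x[:, e], y)
            assert sel.r[e] == pytest.approx(res.statistic, abs=1e-10)
            assert sel.p[e] == pytest.approx(res.pvalue, abs=1e-10)

    def test_covariates_give_partial_correlation(self, rng):
        # oracle: residualize feature and outcome on covariates, then apply
        # the plain correlation test with df reduced by the covariate count
        n, k = 40, 2
        x = rng.standard_normal((n, 3))
        cov = rng.standard_normal((n, k))
        y = x[:, 0] * 0.5 + cov @ np.array([1.0, -2.0]) + rng.standard_normal(n)
        sel = first_stage_select(x, y, covariates=cov)
        design = np.column_stack([np.ones(n), cov])
        for e in range(3):
            xr = x[:, e] - design @ np.linalg.lstsq(design, x[:, e], rcond=None)[0]
            yr = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
            r = float(np.corrcoef(xr, yr)[0, 1])
            df = n - 2 - k
            t = r * np.sqrt(df / (1 - r * r))
            p = 2 * stats.t.sf(abs(t), df)
            assert sel.r[e] == pytest.approx(r, abs=1e-10)
            assert sel.p[e] == pytest.approx(p, abs=1e-10)

    def test_masks_disjoint_and_shrink_with_alpha(self, rng):
        x = rng.standard_normal((30, 50))
        y = rng.standard_normal(30)
        loose = first_stage_select(x, y, config=ModelConfig(alpha_select=0.3))
        tight = first_stage_select(x, y, config=ModelConfig(alpha_select=0.01))
        assert not np.any(loose.positive_mask & loose.negative_mask)
        assert tight.n_positive <= loose.n_positive
        assert tight.n_negative <= loose.n_negative

    def test_constant_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="constant outcome"):
            first_stage_select(rng.standard_normal((10, 2)), np.ones(10))


class TestSummarizeFeatures:
    def test_plain_sum(self):
        x = np.array([[1.5, 2.5, 9.0]])
        sel = make_selection([0.4, 0.6, -0.2], pos=[1, 1, 0])
        s, names, fallback = summarize_features(x, sel, ModelConfig())
        assert s[0, 0] == pytest.approx(4.0)
        assert names == ["sum_positive"] and not fallback

    def test_both_mode_empty_negative_column_zero(self, caplog):
        x = np.array([[1.0, 2.0]])
        sel = make_selection([0.5, 0.5], pos=[1, 1])
        with caplog.at_level("WARNING"):
            s, names, fallback = summarize_features(x, sel, ModelConfig(selection_mode="both"))
        assert s.shape == (1, 2)
        assert s[0, 1] == 0.0 and not fallback
        assert "empty mask" in caplog.text

    def test_r_weighted_sum(self):
        # two features r = (+0.5, -0.5): the sign split puts only the first
        # in the positive mask, so the weighted sum over that mask is 2*0.5
        x = np.array([[2.0, 2.0]])
        sel = make_selection([0.5, -0.5], pos=[1, 0], neg=[0, 1])
        s, _, _ = summarize_features(x, sel, ModelConfig(weighting="r_weighted"))
        assert s[0, 0] == pytest.approx(1.0)

    def test_empty_selection_triggers_fallback(self, caplog):
        x = np.ones((3, 2))
        sel = make_selection([0.1, 0.2])
        with caplog.at_level("WARNING"):
            _, _, fallback = summarize_features(x, sel, ModelConfig())
        assert fallback
        assert "falling back" in caplog.text


class TestSecondStage:
    def test_exact_linear_recovery(self):
        s = np.arange(10.0)[:, None]
        y = 2.0 * s.ravel() + 3.0
        model = fit_second_stage(s, y)
        assert model.beta[0] == pytest.approx(3.0, abs=1e-10)
        assert model.beta[1] == pytest.approx(2.0, abs=1e-10)

    def test_fwl_orthogonal_covariates_same_slope(self, rng):
        # covariates orthogonal to the summary: nuisance-scheme slope equals
        # predictors-scheme slope (Frisch-Waugh-Lovell)
        n = 50
        s = rng.standard_normal((n, 1))
        s -= s.mean()
        cov = rng.standard_normal((n, 1))
        cov -= cov.mean()
        cov -= s * (s.ravel() @ cov.ravel()) / (s.ravel() @ s.ravel())
        y = 1.5 * s.ravel() + 0.7 * cov.ravel() + rng.standard_normal(n)
        m_pred = fit_second_stage(s, y, cov, ModelConfig(covariate_role="predictors", covariates=("age",)))
        m_nuis = fit_second_stage(s, y, cov, ModelConfig(covariate_role="nuisance", covariates=("age",)))
        assert m_nuis.beta[1] == pytest.approx(m_pred.beta[1], abs=1e-8)

    def test_duplicated_covariate_rank_error(self, rng):
        n = 20
        s = rng.standard_normal((n, 1))
        c = rng.standard_normal((n, 1))
        y = rng.standard_normal(n)
        with pytest.raises(ValueError, match="rank"):
            fit_second_stage(
                s, y, np.hstack([c, c]),
                ModelConfig(covariate_role="predictors", covariates=("age", "sex")),
            )


class TestPredict:
    def test_in_sample_predictors_reproduce_fitted(self, rng):
        n = 30
        x = rng.standard_normal((n, 10))
        y = x[:, 0] + rng.standard_normal(n)
        cov = rng.standard_normal((n, 1))
        cfg = ModelConfig(alpha_select=0.5, covariate_role="predictors", covariates=("age",))
        sel = first_stage_select(x, y, cov, cfg)
        s, names, fb = summarize_features(x, sel, cfg)
        model = fit_second_stage(s, y, cov, cfg, selection=sel, summary_names=names, fallback=fb)
        design = np.column_stack([np.ones(n), s, cov])
        fitted = design @ model.beta
        np.testing.assert_allclose(predict(model, x, cov), fitted, atol=1e-10)

    def test_nuisance_equals_predictors_in_sample(self, rng):
        # Frisch-Waugh-Lovell: fitted on the same data, the residualize-
        # and-add-back scheme reproduces the covariates-as-predictors fit
        n = 40
        x = rng.standard_normal((n, 20))
        cov = rng.standard_normal((n, 2))
        y = x[:, 0] - 2 * x[:, 1] + cov @ np.array([1.0, 0.5]) + rng.standard_normal(n)

        def run(role):
            cfg = ModelConfig(alpha_select=0.3, covariate_role=role, covariates=("age", "sex"))
            sel = first_stage_select(x, y, cov, cfg)
            s, names, fb = summarize_features(x, sel, cfg)
            model = fit_second_stage(s, y, cov, cfg, selection=sel, summary_names=names, fallback=fb)
            return predict(model, x, cov, nuisance_source="train")

        np.testing.assert_allclose(run("nuisance"), run("predictors"), atol=1e-8)

    def test_feature_count_mismatch_rejected(self, rng):
        x = rng.standard_normal((20, 5))
        y = x[:, 0] + 0.1 * rng.standard_normal(20)
        sel = first_stage_select(x, y, config=ModelConfig(alpha_select=0.5))
        s, names, fb = summarize_features(x, sel, ModelConfig(alpha_select=0.5))
        model = fit_second_stage(s, y, selection=sel, summary_names=names, fallback=fb)
        with pytest.raises(ValueError, match="mismatch"):
            predict(model, rng.standard_normal((3, 7)))

    def test_single_subject_test_source_rejected(self, rng):
        n = 20
        x = rng.standard_normal((n, 5))
        cov = rng.standard_normal((n, 1))
        y = x[:, 0] + cov.ravel() + 0.1 * rng.standard_normal(n)
        cfg = ModelConfig(alpha_select=0.5, covariate_role="nuisance", covariates=("age",))
        sel = first_stage_select(x, y, cov, cfg)
        s, names, fb = summarize_features(x, sel, cfg)
        model = fit_second_stage(s, y, cov, cfg, selection=sel, summary_names=names, fallback=fb)
        with pytest.raises(ValueError, match="single-subject"):
            predict(model, x[:1], cov[:1], nuisance_source="test")


class TestLoocv:
    def test_noiseless_signal_gives_high_r(self):
        # signal concentrated in two features so each survives selection in
        # every fold; outcome noise off
        cohort = generate_cohort(signal_spec(seed=21, sigma_outcome=0.0, signal_feature_count=2))
        result = loocv(cohort.baseline_features, cohort.phenotypes, ModelConfig())
        assert pearson_r(result.y, result.yhat) > 0.9

    def test_permuted_outcome_mean_r2_nonpositive(self):
        """With the outcome permuted there is nothing to exploit: selection
        overfits each training fold and held-out R^2 is negative on average."""
        rng = np.random.default_rng(2024)
        r2s = []
        cohort = generate_cohort(signal_spec(seed=8, n_subjects=30, n_vertices=100))
        phen = cohort.phenotypes
        for _ in range(50):
            shuffled = phen.copy()
            shuffled["outcome_post"] = rng.permutation(phen["outcome_post"].to_numpy())
            res = loocv(cohort.baseline_features, shuffled, ModelConfig())
            r2s.append(cv_r2(res.y, res.yhat))
        assert np.mean(r2s) <= 0.0

    def test_small_sample_warns(self, rng):
        x = rng.standard_normal((6, 10))
        phen = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(6)],
                "outcome_baseline": [10] * 6,
                "outcome_post": rng.integers(0, 25, 6),
                "age": rng.uniform(8, 17, 6),
                "sex": [0, 1] * 3,
                "fd_mean": [0.1] * 6,
                "fd_pct_above": [5.0] * 6,
            }
        )
        with pytest.warns(UserWarning, match="small"):
            loocv(x, phen, ModelConfig(alpha_select=0.5))

    def test_subject_order_invariance(self, small_edge_cohort):
        cfg = ModelConfig(alpha_select=0.1)
        res = loocv(small_edge_cohort.baseline_features, small_edge_cohort.phenotypes, cfg)
        perm = np.random.default_rng(3).permutation(len(res.y))
        shuffled_phen = small_edge_cohort.phenotypes.iloc[perm].reset_index(drop=True)
        shuffled_x = small_edge_cohort.baseline_features.values[perm]
        res2 = loocv(shuffled_x, shuffled_phen, cfg)
        np.testing.assert_allclose(res2.yhat, res.yhat[perm], atol=1e-10)

    def test_nuisance_covariate_pipeline_runs(self, signal_cohort):
        cfg = ModelConfig(
            covariate_role="nuisance", covariates=("age", "sex", "outcome_baseline")
        )
        res = loocv(signal_cohort.baseline_features, signal_cohort.phenotypes, cfg)
        assert np.all(np.isfinite(res.yhat))
        assert res.fold_positive_masks.shape == (60, 150)


class TestExternalValidate:
    def test_train_as_test_equals_in_sample(self, signal_cohort):
        cfg = ModelConfig()
        res = external_validate(
            signal_cohort.baseline_features,
            signal_cohort.phenotypes,
            signal_cohort.baseline_features,
            signal_cohort.phenotypes,
            cfg,
        )
        y = outcome_vector(signal_cohort.phenotypes, "post")
        sel = first_stage_select(signal_cohort.baseline_features, y)
        s, names, fb = summarize_features(signal_cohort.baseline_features, sel, cfg)
        model = fit_second_stage(s, y, selection=sel, summary_names=names, fallback=fb)
        np.testing.assert_allclose(res.yhat, predict(model, signal_cohort.baseline_features), atol=1e-10)

    def test_shared_truth_cohorts_comparable_to_loocv(self):
        # one 120-subject draw split in half: same generative truth on both
        # sides, so external-validation r should track the LOOCV r
        cohort = generate_cohort(signal_spec(seed=31, n_subjects=120))
        half = 60
        fa, fb = cohort.baseline_features.values[:half], cohort.baseline_features.values[half:]
        pa = cohort.phenotypes.iloc[:half].reset_index(drop=True)
        pb = cohort.phenotypes.iloc[half:].reset_index(drop=True)
        cfg = ModelConfig()
        r_loo = pearson_r(*(lambda r: (r.y, r.yhat))(loocv(fa, pa, cfg)))
        r_ext = pearson_r(*(lambda r: (r.y, r.yhat))(external_validate(fa, pa, fb, pb, cfg)))
        assert abs(r_ext - r_loo) < 0.15

    def test_feature_mismatch_rejected(self, rng):
        phen = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(10)],
                "outcome_baseline": [10] * 10,
                "outcome_post": rng.integers(0, 25, 10),
                "age": rng.uniform(8, 17, 10),
                "sex": [0, 1] * 5,
                "fd_mean": [0.1] * 10,
                "fd_pct_above": [5.0] * 10,
            }
        )
        with pytest.raises(ValueError, match="mismatch"):
            external_validate(
                rng.standard_normal((10, 5)), phen, rng.standard_normal((10, 6)), phen
            )


class TestFeatureFrequency:
    def test_always_selected_feature_has_fraction_one(self, rng):
        res = loocv_stub(rng, always=0)
        table = feature_frequency(res, min_frac=0.5)
        row = table[(table["feature_index"] == 0) & (table["sign"] == "positive")]
        assert row["fraction"].iloc[0] == 1.0

    def test_below_threshold_excluded(self, rng):
        res = loocv_stub(rng, always=0, sometimes=(1, 3))
        table = feature_frequency(res, min_frac=0.5)
        assert 1 not in table["feature_index"].tolist()

    def test_external_result_rejected(self, rng):
        from cpmkit.model import PredictionResult

        res = PredictionResult(y=np.zeros(3), yhat=np.zeros(3), subject_ids=list("abc"))
        with pytest.raises(ValueError, match="LOOCV"):
            feature_frequency(res)

    def test_signal_features_dominate_frequency_table(self, signal_cohort):
        res = loocv(signal_cohort.baseline_features, signal_cohort.phenotypes, ModelConfig())
        table = feature_frequency(res, min_frac=0.5)
        frequent = set(table[table["sign"] == "positive"]["feature_index"])
        truth = set(signal_cohort.truth["signal_indices"])
        assert truth <= frequent
        # everything else in the table is rare noise
        assert len(frequent - truth) <= len(truth)


def loocv_stub(rng, always=None, sometimes=()):
    """A hand-built LOOCV result with controlled per-fold masks."""
    from cpmkit.model import PredictionResult

    n, m = 10, 5
    pos = np.zeros((n, m), bool)
    if always is not None:
        pos[:, always] = True
    for feat, count in [sometimes] if sometimes else []:
        pos[:count, feat] = True
    return PredictionResult(
        y=rng.standard_normal(n),
        yhat=rng.standard_normal(n),
        subject_ids=[f"s{i}" for i in range(n)],
        fold=np.arange(n),
        fold_positive_masks=pos,
        fold_negative_masks=np.zeros((n, m), bool),
    )


class TestMotionCheck:
    def test_exhaustive_agrees_with_monte_carlo(self, rng):
        fd = rng.uniform(0.05, 0.3, 5)
        y = rng.integers(0, 25, 5).astype(float)
        _, p_ex = motion_check(fd, y, exhaustive=True)
        _, p_mc = motion_check(fd, y, n_perm=100_000, seed=0, exhaustive=False)
        assert abs(p_ex - p_mc) < 0.01

    def test_identical_vectors_minimal_p(self):
        x = np.array([0.1, 1.3, 2.2, 4.7, 9.1])
        r, p = motion_check(x, x, exhaustive=True)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 120.0)

    def test_p_uniform_under_independence(self):
        rng = np.random.default_rng(55)
        ps = [
            motion_check(
                rng.standard_normal(15), rng.standard_normal(15), n_perm=999, seed=int(s)
            )[1]
            for s in rng.integers(0, 2**31 - 1, size=200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            motion_check(np.ones(6), np.arange(6.0))
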