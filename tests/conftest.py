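import numpy as np
import pytest

from cpmkit import CohortSpec, generate_cohort


def signal_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Sparse strong-signal, low-noise regime: a few features carry most of
    the outcome variance, no covariate effects."""
    params = dict(
        n_subjects=60,
        n_nodes=None,
        n_vertices=150,
        signal_feature_count=4,
        beta_signal=5.0,
        beta_age=0.0,
        beta_sex=0.0,
        beta_baseline=0.0,
        sigma_outcome=0.5,
        intercept=12.0,
        seed=seed,
    )
    params.update(overrides)
    return CohortSpec(**params)


def null_spec(seed: int = 0, **overrides) -> CohortSpec:
    """No signal features and no covariate effects: outcome is pure noise."""
    params = dict(
        n_subjects=30,
        n_nodes=None,
        n_vertices=100,
        signal_feature_count=0,
        beta_signal=0.0,
        beta_age=0.0,
        beta_sex=0.0,
        beta_baseline=0.0,
        sigma_outcome=3.0,
        intercept=9.0,
        seed=seed,
    )
    params.update(overrides)
    return CohortSpec(**params)


@pytest.fixture(scope="session")
def signal_cohort():
    return generate_cohort(signal_spec(seed=11))


@pytest.fixture(scope="session")
def small_edge_cohort():
    """Edge-feature cohort small enough for fast LOOCV and fingerprinting."""
    return generate_cohort(
        CohortSpec(n_subjects=24, n_nodes=15, signal_feature_count=5, seed=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
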