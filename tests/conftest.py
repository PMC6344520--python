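"""Shared fixtures: small synthetic cohorts and scaled-down learner settings.

The scaled-down learner configuration keeps forests and random-search
budgets small enough for a desk-scale test run while leaving the method
itself untouched (tuning still uses 10-fold inner CV and the one-SE rule;
final forests are larger than tuning forests because tree count is a
variance knob, not a tuned hyperparameter).
"""

import numpy as np
import pytest

from motionstack import CohortSpec, generate_cohort, knn_impute, make_learners

# reduced search breadth / tree counts for desk-scale runs
SCALED_OVERRIDES = {
    "ENET": {"search_budget": 12},
    "PCR": {"search_budget": 8},
    "PLS": {"search_budget": 8},
    "SVR": {"search_budget": 8},
    "RF": {"n_trees": 300, "n_trees_tune": 40, "vi_max_trees": 80, "search_budget": 3},
    "CF": {"n_trees": 80, "n_trees_tune": 15, "vi_max_trees": 80, "search_budget": 2},
}

# still smaller settings for structural (non-statistical) checks
TINY_OVERRIDES = {
    "ENET": {"search_budget": 3},
    "PCR": {"search_budget": 3},
    "PLS": {"search_budget": 3},
    "SVR": {"search_budget": 3},
    "RF": {"n_trees": 30, "n_trees_tune": 15, "search_budget": 2},
    "CF": {"n_trees": 15, "n_trees_tune": 8, "search_budget": 2},
}


@pytest.fixture(scope="session")
def scaled_learners():
    return make_learners(overrides=SCALED_OVERRIDES)


@pytest.fixture()
def tiny_learners():
    return make_learners(overrides=TINY_OVERRIDES)


@pytest.fixture(scope="session")
def default_cohort():
    """The canonical study-sized cohort (n=464, 120 predictors)."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def default_cohort_imputed(default_cohort):
    return knn_impute(default_cohort.features, k=5)


@pytest.fixture()
def small_cohort():
    """A small cohort for fast structural tests."""
    return generate_cohort(
        CohortSpec(n_subjects=80, n_physical=5, n_psych=10, n_drug_like=4, seed=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
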