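import numpy as np
import pandas as pd
import pytest

import dietmsm as dm


@pytest.fixture(scope="session")
def confounded_truth():
    return dm.generate_truth("confounded_positive", n=4000, seed=42)


@pytest.fixture(scope="session")
def confounded_cohort(confounded_truth):
    return dm.generate_cohort(confounded_truth)


@pytest.fixture(scope="session")
def null_truth():
    return dm.generate_truth("null", n=4000, seed=7)


@pytest.fixture(scope="session")
def null_cohort(null_truth):
    return dm.generate_cohort(null_truth)


@pytest.fixture(scope="session")
def fitted_weights(confounded_cohort):
    """Combined IPW weights for the confounded cohort's total-dairy exposure."""
    from dietmsm.pipeline import DEFAULT_CENSORING_COVARIATES, DEFAULT_CONFOUNDERS

    tw = dm.TreatmentWeightModel(
        confounded_cohort, "total_dairy", DEFAULT_CONFOUNDERS
    ).fit()
    cw = dm.CensoringWeightModel(confounded_cohort, DEFAULT_CENSORING_COVARIATES).fit()
    return dm.combine_weights(tw.sw_a, cw.sw_c)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def item_intake_table(rng):
    """Random nonnegative item-level intake table over the default map items."""
    food_map = dm.default_food_group_map()
    items = list(food_map.items)
    data = rng.gamma(2.0, 50.0, size=(40, len(items)))
    return pd.DataFrame(data, columns=items)
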