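"""Stabilized IPW engine: density-ratio weights, censoring weights, truncation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

import dietmsm as dm
from dietmsm.pipeline import DEFAULT_CENSORING_COVARIATES, DEFAULT_CONFOUNDERS
from dietmsm.weights import (
    CensoringWeightModel,
    TreatmentWeightModel,
    combine_weights,
    effective_sample_size,
    truncate_weights,
)


class TestTruncation:
    def test_equal_weights_unchanged(self):
        w, cap = truncate_weights(pd.Series([2.0] * 10))
        assert (w == 2.0).all() and cap == 2.0

    def test_enumerated_clipping_1_to_1000(self):
        # lower-order-statistic 99.5th percentile of 1..1000 is 995
        # -> exactly 996..1000 clipped
        w = pd.Series(np.arange(1, 1001, dtype=float))
        truncated, cap = truncate_weights(w, percentile=99.5)
        assert cap == 995.0
        n_clipped = int((w > cap).sum())
        assert n_clipped == 5
        assert (truncated[w > cap] == cap).all()
        assert (truncated[w <= cap] == w[w <= cap]).all()

    def test_idempotent(self):
        w = pd.Series(np.random.default_rng(1).gamma(1.0, 1.0, 500))
        once, _ = truncate_weights(w)
        twice, _ = truncate_weights(once)
        pd.testing.assert_series_equal(once, twice)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            truncate_weights(pd.Series(dtype=float))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            truncate_weights(pd.Series([1.0, 0.0]))


class TestTreatmentWeights:
    def test_hand_computed_six_row_fixture(self):
        """SW_A matches independent normal-density-ratio arithmetic to 1e-10."""
        data = pd.DataFrame(
            {
                "a": [100.0, 150.0, 200.0, 250.0, 300.0, 350.0],
                "x": [0.0, 0.0, 1.0, 1.0, 2.0, 2.0],
            }
        )
        res = TreatmentWeightModel(data, "a", ["x"]).fit()
        # oracle: numpy lstsq OLS + explicit normal densities
        X = np.column_stack([np.ones(6), data["x"]])
        beta, *_ = np.linalg.lstsq(X, data["a"], rcond=None)
        fitted = X @ beta
        resid_sd = np.sqrt(((data["a"] - fitted) ** 2).sum() / (6 - 2))
        num = norm.pdf(data["a"], data["a"].mean(), data["a"].std(ddof=1))
        den = norm.pdf(data["a"], fitted, resid_sd)
        np.testing.assert_allclose(res.sw_a, num / den, atol=1e-10)

    def test_exposure_independent_of_confounders_gives_unit_weights(self):
        rng = np.random.default_rng(5)
        n = 2000
        data = pd.DataFrame(
            {"a": rng.normal(300, 60, n), "group": rng.choice(["p", "q"], n)}
        )
        res = TreatmentWeightModel(data, "a", ["group"]).fit()
        # fitted slopes ~ 0 -> density ratio ~ 1 for everyone
        assert res.sw_a.mean() == pytest.approx(1.0, abs=0.02)
        assert res.sw_a.std() < 0.05

    def test_mean_near_one_on_well_specified_cohort(self, confounded_cohort):
        res = TreatmentWeightModel(
            confounded_cohort, "total_dairy", DEFAULT_CONFOUNDERS
        ).fit()
        assert 0.9 < res.sw_a.mean() < 1.1

    def test_permutation_invariance(self, confounded_cohort):
        res = TreatmentWeightModel(
            confounded_cohort, "total_dairy", DEFAULT_CONFOUNDERS
        ).fit()
        shuffled = confounded_cohort.sample(frac=1.0, random_state=3)
        res2 = TreatmentWeightModel(shuffled, "total_dairy", DEFAULT_CONFOUNDERS).fit()
        pd.testing.assert_series_equal(
            res2.sw_a.sort_index(), res.sw_a.sort_index(), atol=1e-10, rtol=0
        )

    def test_incomplete_rows_get_fallback_unit_weight(self, confounded_cohort):
        data = confounded_cohort.head(500).copy()
        data.loc[data.index[:10], "smoking"] = np.nan
        res = TreatmentWeightModel(data, "total_dairy", DEFAULT_CONFOUNDERS).fit()
        flagged = res.weightset.frame["incomplete_flag"] == 1
        assert flagged.sum() == 10
        assert (res.weightset.frame.loc[flagged, "sw_a"] == 1.0).all()

    def test_deterministic_exposure_rejected(self):
        data = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "x": [0.0, 1.0, 0.0, 1.0]})
        with pytest.raises(ValueError, match="residual SD|deterministic"):
            TreatmentWeightModel(data, "a", ["x"]).fit()


class TestCensoringWeights:
    def test_no_dropout_gives_unit_weights(self):
        data = pd.DataFrame({"followed": [1, 1, 1], "sex": ["f", "m", "f"]})
        res = CensoringWeightModel(data, ["sex"]).fit()
        assert (res.sw_c == 1.0).all()

    def test_known_logistic_fixture_matches_closed_form(self):
        """Saturated 2-covariate design: fitted cell probabilities equal cell
        frequencies, so SW_C = P(C=1) / cell frequency exactly."""
        rows = []
        # cells: (x1, x2) with chosen follow-up counts out of 50
        cells = {(0, 0): 40, (0, 1): 30, (1, 0): 45, (1, 1): 35}
        for (x1, x2), k in cells.items():
            for i in range(50):
                rows.append({"x1": x1, "x2": x2, "x12": x1 * x2, "followed": 1 if i < k else 0})
        data = pd.DataFrame(rows)
        res = CensoringWeightModel(data, ["x1", "x2", "x12"]).fit()
        p_marg = data["followed"].mean()
        for (x1, x2), k in cells.items():
            cell = (data["x1"] == x1) & (data["x2"] == x2) & (data["followed"] == 1)
            expected = p_marg / (k / 50)
            np.testing.assert_allclose(res.sw_c[cell], expected, rtol=1e-6)

    def test_zero_coefficient_generator_weights_near_one(self):
        rng = np.random.default_rng(11)
        n = 5000
        data = pd.DataFrame(
            {
                "followed": rng.binomial(1, 0.8, n),
                "sex": rng.choice(["f", "m"], n),
                "age_group": rng.choice(["<70", "70-74", ">74"], n),
            }
        )
        res = CensoringWeightModel(data, ["sex", "age_group"]).fit()
        followed = data["followed"] == 1
        assert res.sw_c[followed].mean() == pytest.approx(1.0, abs=0.02)

    def test_weights_only_for_followed(self, confounded_cohort):
        res = CensoringWeightModel(confounded_cohort, DEFAULT_CENSORING_COVARIATES).fit()
        not_followed = confounded_cohort["followed"] == 0
        assert res.sw_c[not_followed].isna().all()
        assert res.sw_c[~not_followed].notna().all()

    def test_perfect_separation_raises(self):
        data = pd.DataFrame(
            {"followed": [1] * 20 + [0] * 20, "x": [1.0] * 20 + [0.0] * 20}
        )
        with pytest.raises(RuntimeError, match="separation|fit"):
            CensoringWeightModel(data, ["x"]).fit()


class TestCombineWeights:
    def test_unit_censoring_reduces_to_truncated_treatment(self):
        rng = np.random.default_rng(2)
        sw_a = pd.Series(rng.gamma(2.0, 0.5, 400))
        sw_c = pd.Series(1.0, index=sw_a.index)
        out = combine_weights(sw_a, sw_c)
        expected, _ = truncate_weights(sw_a)
        np.testing.assert_allclose(out.frame["w"], expected, rtol=1e-12)

    def test_product_matches_manual_arithmetic(self):
        rng = np.random.default_rng(8)
        sw_a = pd.Series(rng.gamma(2.0, 0.5, 300))
        sw_c = pd.Series(rng.gamma(3.0, 0.33, 300))
        out = combine_weights(sw_a, sw_c, percentile=99.5)
        ta, _ = truncate_weights(sw_a, 99.5)
        tc, _ = truncate_weights(sw_c, 99.5)
        manual, _ = truncate_weights(ta * tc, 99.5)
        np.testing.assert_allclose(out.frame["w"].dropna(), manual, rtol=1e-12)

    def test_combined_only_for_rows_with_both(self):
        sw_a = pd.Series([1.0, 1.2, 0.9])
        sw_c = pd.Series([1.1, np.nan, 1.0])
        out = combine_weights(sw_a, sw_c)
        assert out.frame["w"].notna().tolist() == [True, False, True]

    def test_mean_combined_weight_near_one(self, fitted_weights):
        assert 0.9 < fitted_weights.frame["w"].dropna().mean() < 1.1

    def test_caps_recorded(self, fitted_weights):
        assert set(fitted_weights.caps) == {"sw_a", "sw_c", "w"}
        w = fitted_weights.frame["w"].dropna()
        assert (w <= fitted_weights.caps["w"] + 1e-12).all()


class TestEffectiveSampleSize:
    def test_bounds_and_equality_condition(self, rng):
        w = rng.gamma(2.0, 0.5, 200)
        assert effective_sample_size(w) <= 200
        assert effective_sample_size(np.full(200, 3.7)) == pytest.approx(200.0)

    def test_diagnostics_exposed(self, fitted_weights):
        diag = fitted_weights.diagnostics()
        n = diag["w"]["n"]
        assert 0 < diag["w"]["ess"] <= n
        assert diag["truncation_percentile"] == 99.5
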