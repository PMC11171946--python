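"""Regression stages against the closed-form contingency-table oracle."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from dynaperv import (
    CATEGORIES,
    CohortParams,
    OutcomeLinear,
    PassesPoisson,
    RecanalizationLogistic,
    TwoByTwo,
    category_odds_ratios,
    fit_outcome_linear,
    fit_passes_poisson,
    fit_recanalization_logistic,
    fit_sp_logistic,
    odds_ratio_2x2,
    simulate_cohort,
)
from dynaperv.errors import SeparationError, ZeroCellError


def counts_cohort(successes: dict[str, int], sizes: dict[str, int]) -> pd.DataFrame:
    """Deterministic cohort realizing exact per-category success counts."""
    rows = []
    for cat, n in sizes.items():
        k = successes[cat]
        for i in range(n):
            rows.append({"dp_category": cat, "success": i < k,
                         "clot_length_mm": 15.0 + (i % 7)})
    return pd.DataFrame(rows)


# The observed per-group recanalization counts: 39/49, 15/22, 29/37, 26/29.
OBSERVED_SUCCESSES = {"C_NE": 39, "C_NW": 15, "C_W": 29, "C_LE": 26}
OBSERVED_SIZES = {"C_NE": 49, "C_NW": 22, "C_W": 37, "C_LE": 29}


class TestOddsRatio2x2:
    @pytest.mark.parametrize(
        "table, expected_or",
        [
            (TwoByTwo(26, 3, 15, 7), 4.04),   # late enhancement vs reference
            (TwoByTwo(39, 10, 15, 7), 1.82),  # no enhancement vs reference
            (TwoByTwo(29, 8, 15, 7), 1.69),   # washout vs reference
            (TwoByTwo(5, 5, 5, 5), 1.00),     # symmetry
        ],
    )
    def test_cross_product_examples(self, table, expected_or):
        r = odds_ratio_2x2(table)
        assert r.estimate == pytest.approx(expected_or, abs=0.005)
        assert r.ci_low <= r.estimate <= r.ci_high

    def test_wald_machinery(self):
        r = odds_ratio_2x2(TwoByTwo(26, 3, 15, 7))
        assert r.se_log == pytest.approx(np.sqrt(1 / 26 + 1 / 3 + 1 / 15 + 1 / 7))
        assert r.p_value == pytest.approx(0.067, abs=0.001)

    def test_zero_cell_reported_not_returned(self):
        with pytest.raises(ZeroCellError, match="degenerate"):
            odds_ratio_2x2(TwoByTwo(10, 0, 5, 5))
        r = odds_ratio_2x2(TwoByTwo(10, 0, 5, 5), correction="haldane")
        assert r.corrected and np.isfinite(r.estimate)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 2, 3, 4)


class TestRecanalizationLogistic:
    def test_reproduces_observed_odds_ratios(self):
        cohort = counts_cohort(OBSERVED_SUCCESSES, OBSERVED_SIZES)
        res = fit_recanalization_logistic(cohort).set_index("term")
        assert res.loc["C_NE", "estimate"] == pytest.approx(1.82, abs=0.005)
        assert res.loc["C_W", "estimate"] == pytest.approx(1.69, abs=0.005)
        assert res.loc["C_LE", "estimate"] == pytest.approx(4.04, abs=0.005)

    def test_unadjusted_fit_equals_2x2_oracle(self, default_cohort):
        """Saturated categorical logistic == cross-product ratios to 1e-6."""
        fit = fit_recanalization_logistic(default_cohort).set_index("term")
        oracle = category_odds_ratios(default_cohort).set_index("term")
        for cat in oracle.index:
            assert fit.loc[cat, "estimate"] == pytest.approx(
                oracle.loc[cat, "estimate"], rel=1e-6
            )

    def test_null_effect_gives_unit_ors(self):
        rng = np.random.default_rng(7)
        n = 2000
        cohort = pd.DataFrame({
            "dp_category": rng.choice(CATEGORIES, n),
            "success": rng.random(n) < 0.8,
            "clot_length_mm": rng.uniform(3, 61, n),
        })
        res = fit_recanalization_logistic(cohort)
        assert np.allclose(res["estimate"], 1.0, atol=0.35)

    def test_adjusting_for_clot_length_keeps_category_terms(self):
        cohort = counts_cohort(OBSERVED_SUCCESSES, OBSERVED_SIZES)
        res = fit_recanalization_logistic(cohort, adjust_clot_length=True)
        assert set(res["term"]) == {"C_NE", "C_W", "C_LE", "clot_length_mm"}

    def test_complete_separation_names_category(self):
        successes = dict(OBSERVED_SUCCESSES, C_LE=29)  # all successes
        cohort = counts_cohort(successes, OBSERVED_SIZES)
        with pytest.raises(SeparationError, match="C_LE"):
            fit_recanalization_logistic(cohort)

    def test_reference_level_relabelling_is_consistent(self, default_cohort):
        """OR_{A vs B} = OR_{A vs ref} / OR_{B vs ref} for any reference."""
        r_nw = fit_recanalization_logistic(default_cohort, reference="C_NW").set_index("term")
        r_ne = fit_recanalization_logistic(default_cohort, reference="C_NE").set_index("term")
        direct = r_ne.loc["C_LE", "estimate"]
        indirect = r_nw.loc["C_LE", "estimate"] / r_nw.loc["C_NE", "estimate"]
        assert direct == pytest.approx(indirect, rel=1e-6)

    def test_estimator_api(self, default_cohort):
        est = RecanalizationLogistic(reference="C_NW")
        assert est.get_params()["adjust_clot_length"] is False
        est.fit(default_cohort)
        assert hasattr(est, "results_") and len(est.results_) == 3


class TestStandardPerviousnessLogistic:
    def test_independent_predictor_gives_unit_or(self):
        rng = np.random.default_rng(1)
        n = 20_000
        cohort = pd.DataFrame({
            "success": rng.random(n) < 0.8,
            "delta_na": rng.normal(10, 15, n),
            "delta_nv": rng.normal(7, 10, n),
        })
        res = fit_sp_logistic(cohort).set_index("term")
        assert res.loc["delta_na", "estimate"] == pytest.approx(1.00, abs=0.01)
        assert res.loc["delta_nv", "estimate"] == pytest.approx(1.00, abs=0.01)

    def test_injected_slope_recovered(self):
        rng = np.random.default_rng(2)
        n = 5000
        dna = rng.normal(10, 15, n)
        dnv = rng.normal(7, 10, n)
        logit = -0.5 + 0.05 * dna
        p = 1 / (1 + np.exp(-logit))
        cohort = pd.DataFrame({
            "success": rng.random(n) < p, "delta_na": dna, "delta_nv": dnv,
        })
        res = fit_sp_logistic(cohort).set_index("term")
        lo, hi = res.loc["delta_na", ["ci_low", "ci_high"]]
        assert lo <= np.exp(0.05) <= hi

    def test_constant_predictor_raises(self):
        cohort = pd.DataFrame({
            "success": [0, 1] * 10, "delta_na": 5.0, "delta_nv": np.arange(20.0),
        })
        with pytest.raises(ValueError, match="zero variance"):
            fit_sp_logistic(cohort)


class TestOutcomeLinear:
    def test_outcome_equal_to_baseline_gives_zero_betas(self):
        rng = np.random.default_rng(3)
        n = 400
        admit = rng.integers(0, 40, n).astype(float)
        cohort = pd.DataFrame({
            "dp_category": rng.choice(CATEGORIES, n),
            "nihss_admit": admit,
            "nihss_discharge": admit,
        })
        res = fit_outcome_linear(cohort, "nihss_discharge").set_index("term")
        for cat in ("C_NE", "C_W", "C_LE"):
            assert res.loc[cat, "estimate"] == pytest.approx(0.0, abs=1e-8)
        assert res.loc["nihss_admit", "estimate"] == pytest.approx(1.0, abs=1e-8)

    def test_complete_case_denominator(self, default_cohort):
        res = fit_outcome_linear(default_cohort, "nihss_discharge")
        assert res["n_obs"].iloc[0] == 111  # 137 - 26 deaths
        res_mrs = fit_outcome_linear(default_cohort, "mrs_3mo")
        assert res_mrs["n_obs"].iloc[0] == 76  # 137 - 26 - 35

    def test_single_category_no_contrast(self):
        cohort = pd.DataFrame({
            "dp_category": ["C_NW"] * 20,
            "nihss_admit": np.arange(20.0),
            "nihss_discharge": np.arange(20.0),
        })
        with pytest.raises(ValueError):
            fit_outcome_linear(cohort, "nihss_discharge")

    def test_thin_category_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        n = 120
        cohort = pd.DataFrame({
            "dp_category": rng.choice(["C_NW", "C_NE"], n),
            "nihss_admit": rng.integers(0, 40, n).astype(float),
        })
        cohort["nihss_discharge"] = cohort["nihss_admit"] - 2
        thin = pd.DataFrame({
            "dp_category": ["C_LE"], "nihss_admit": [10.0], "nihss_discharge": [5.0],
        })
        cohort = pd.concat([cohort, thin], ignore_index=True)
        with pytest.warns(UserWarning, match="C_LE"):
            res = fit_outcome_linear(cohort, "nihss_discharge")
        assert "C_LE" not in set(res["term"])

    def test_estimator_api_default_baselines(self):
        assert OutcomeLinear("mrs_3mo")._BASELINES["mrs_3mo"] == "mrs_admit"
        with pytest.raises(ValueError, match="baseline"):
            OutcomeLinear("unknown_outcome").fit(pd.DataFrame())


class TestPassesPoisson:
    def test_saturated_fit_equals_group_mean_ratios(self, default_cohort):
        res = fit_passes_poisson(default_cohort).set_index("term")
        means = default_cohort.dropna(subset=["n_passes"]).groupby(
            "dp_category")["n_passes"].mean()
        for cat in ("C_NE", "C_W", "C_LE"):
            assert res.loc[cat, "estimate"] == pytest.approx(
                means[cat] / means["C_NW"], rel=1e-6
            )

    def test_equal_means_give_unit_rate_ratios(self):
        rng = np.random.default_rng(5)
        n = 8000
        cohort = pd.DataFrame({
            "dp_category": rng.choice(CATEGORIES, n),
            "n_passes": (1 + rng.poisson(1.4, n)).astype(float),
        })
        res = fit_passes_poisson(cohort)
        assert np.allclose(res["estimate"], 1.0, atol=0.06)

    def test_no_intervention_patients_excluded(self, default_cohort):
        res = fit_passes_poisson(default_cohort)
        assert res["n_obs"].iloc[0] == 127  # 137 - 10 without intervention

    def test_estimator_api(self, default_cohort):
        est = PassesPoisson().fit(default_cohort)
        assert set(est.results_["term"]) == {"C_NE", "C_W", "C_LE"}


def test_injected_poisson_rate_ratio_recovered():
    params = dataclasses.replace(
        CohortParams(),
        passes_mean={"C_NE": 2.7, "C_NW": 2.7, "C_W": 2.7, "C_LE": 2.275},
    ).scaled(40)
    cohort = simulate_cohort(params, seed=6)
    res = fit_passes_poisson(cohort).set_index("term")
    # injected rate ratio (2.275 - 1) vs (2.7 - 1) on the shifted scale ~ 2.275/2.7
    lo, hi = res.loc["C_LE", ["ci_low", "ci_high"]]
    assert lo <= 2.275 / 2.7 <= hi
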