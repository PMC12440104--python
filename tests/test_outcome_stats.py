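import math

import numpy as np
import pandas as pd
import pytest
from helpers import bh_step_up, fisher_p_enumeration, mannwhitney_p_enumeration

from pgin.exceptions import ParameterError
from pgin.outcome_stats import (
    benjamini_hochberg,
    compare_groups,
    derive_groups,
    enrichment_test,
    fit_cox,
    partial_effect_curves,
)


class TestDeriveGroups:
    @pytest.mark.parametrize(
        "ga,pe,expected",
        [(33.9, True, "EP-PE"), (34.0, False, "NTT-N"), (40.0, True, "NTT-PE"), (20.0, False, "EP-N")],
    )
    def test_boundary_is_strict_34_weeks(self, ga, pe, expected):
        meta = pd.DataFrame({"ga_weeks": [ga], "pe": [pe]}, index=["s"])
        assert derive_groups(meta).loc["s", "group"] == expected

    def test_missing_ga_is_row_error(self):
        meta = pd.DataFrame({"ga_weeks": [np.nan], "pe": [True]}, index=["s"])
        with pytest.raises(ParameterError, match="s"):
            derive_groups(meta)


class TestMannWhitney:
    def test_three_vs_three_exact_minimum_p(self):
        v = pd.Series([1, 2, 3, 4, 5, 6.0])
        lab = pd.Series(["a"] * 3 + ["b"] * 3)
        out = compare_groups(v, lab)
        assert out["p"].iloc[0] == pytest.approx(0.1)

    @pytest.mark.parametrize("m,n", [(3, 3), (4, 5), (6, 4), (8, 7)])
    def test_exact_p_matches_enumeration(self, m, n, rng):
        x = rng.normal(size=m)
        y = rng.normal(size=n) + 0.5
        v = pd.Series(np.concatenate([x, y]))
        lab = pd.Series(["a"] * m + ["b"] * n)
        out = compare_groups(v, lab)
        assert out["p"].iloc[0] == pytest.approx(mannwhitney_p_enumeration(x, y), abs=1e-12)

    def test_one_sided_direction(self, rng):
        x = rng.normal(size=10) + 3
        y = rng.normal(size=10)
        v = pd.Series(np.concatenate([x, y]))
        lab = pd.Series(["hi"] * 10 + ["lo"] * 10)
        greater = compare_groups(v, lab, sided="one", alternative_greater_first=True)
        less = compare_groups(v, lab, sided="one", alternative_greater_first=False)
        assert greater["p"].iloc[0] < 0.01 < less["p"].iloc[0]

    def test_empty_group_rejected(self):
        v = pd.Series([1.0, 2.0])
        lab = pd.Series(["a", "a"])
        with pytest.raises(ParameterError):
            compare_groups(v, lab, pairs=[("a", "b")])

    def test_type_i_error_calibrated_under_null(self, rng):
        """Identical distributions -> ~5% rejections at alpha 0.05."""
        reps, rej = 400, 0
        for _ in range(reps):
            v = pd.Series(rng.normal(size=60))
            lab = pd.Series(["a"] * 30 + ["b"] * 30)
            rej += compare_groups(v, lab)["p"].iloc[0] < 0.05
        assert 0.03 <= rej / reps <= 0.07


class TestBenjaminiHochberg:
    def test_textbook_vector(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_step_up_definition_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 12))
            assert np.allclose(benjamini_hochberg(p), bh_step_up(list(p)))

    def test_monotone_and_capped(self, rng):
        p = np.sort(rng.uniform(size=30))
        adj = benjamini_hochberg(p)
        assert (np.diff(adj) >= -1e-15).all() and (adj <= 1).all()


class TestFisher:
    def test_cross_product_odds_ratio(self):
        r = enrichment_test(table=[[2, 1], [1, 2]])
        assert r.sample_odds_ratio == pytest.approx(4.0)

    def test_published_style_table(self):
        r = enrichment_test(table=[[27, 11], [18, 56]])
        assert r.sample_odds_ratio == pytest.approx(27 * 56 / (11 * 18))
        assert r.p_value == pytest.approx(fisher_p_enumeration(27, 11, 18, 56), rel=1e-9)

    def test_perfect_separation_infinite_or(self):
        r = enrichment_test(table=[[5, 0], [0, 5]])
        assert math.isinf(r.sample_odds_ratio) and r.undefined_or
        assert r.p_value == pytest.approx(2 / math.comb(10, 5))

    def test_empty_margin_keeps_p(self):
        r = enrichment_test(table=[[0, 0], [3, 4]])
        assert r.undefined_or and r.p_value == pytest.approx(1.0)

    def test_flag_vectors_build_table(self):
        carrier = [True, True, False, False]
        outcome = [True, False, True, False]
        r = enrichment_test(carrier, outcome)
        assert r.table == ((1, 1), (1, 1))

    def test_enumeration_oracle_over_small_margins(self):
        """p equals hypergeometric enumeration for a sweep of small tables."""
        for a in range(0, 6):
            for b in range(0, 6):
                for c in range(0, 6):
                    for d in range(0, 6):
                        if a + b + c + d == 0:
                            continue
                        r = enrichment_test(table=[[a, b], [c, d]])
                        assert r.p_value == pytest.approx(
                            fisher_p_enumeration(a, b, c, d), rel=1e-9, abs=1e-12
                        ), (a, b, c, d)


class TestCox:
    def test_planted_log_hr_recovery(self, survival_cohort):
        df, truth = survival_cohort
        fit = fit_cox(df, ["z_instability", "z_hypoxia"], penalizer_grid=(0.0,),
                      k_folds=None, check_ph=False)
        assert fit.coefficients["z_instability"] == pytest.approx(
            truth["log_hr_instability"], abs=0.15
        )
        assert fit.hazard_ratios["z_instability"] == pytest.approx(
            math.exp(fit.coefficients["z_instability"])
        )

    def test_duplicating_samples_keeps_point_estimate(self, survival_cohort):
        """Likelihood proportionality: duplicating every sample leaves the
        estimate unchanged up to the Efron tie correction the duplicated
        event times trigger (O(1/n))."""
        df, _ = survival_cohort
        sub = df.iloc[:120]
        fit1 = fit_cox(sub, ["z_instability"], penalizer_grid=(0.0,), k_folds=None, check_ph=False)
        fit2 = fit_cox(pd.concat([sub, sub], ignore_index=True), ["z_instability"],
                       penalizer_grid=(0.0,), k_folds=None, check_ph=False)
        assert fit1.coefficients["z_instability"] == pytest.approx(
            fit2.coefficients["z_instability"], rel=0.01
        )

    def test_penalizer_selected_from_grid(self, survival_cohort):
        df, _ = survival_cohort
        fit = fit_cox(df.iloc[:150], ["z_instability", "z_hypoxia"],
                      penalizer_grid=(0.0, 0.01, 0.1, 1.0), k_folds=5, seed=1, check_ph=False)
        assert fit.penalizer in (0.0, 0.01, 0.1, 1.0)

    def test_missing_feature_values_rejected(self, survival_cohort):
        df, _ = survival_cohort
        df = df.iloc[:50].copy()
        df.loc[df.index[0], "z_instability"] = np.nan
        with pytest.raises(ParameterError):
            fit_cox(df, ["z_instability"], penalizer_grid=(0.0,), k_folds=None)


class TestPartialEffects:
    def _fit(self, survival_cohort):
        df, _ = survival_cohort
        return fit_cox(df, ["z_instability", "z_hypoxia"], penalizer_grid=(0.0,),
                       k_folds=None, check_ph=False)

    def test_high_percentile_curve_dominates_for_positive_coef(self, survival_cohort):
        fit = self._fit(survival_cohort)
        curves = partial_effect_curves(fit, "z_instability", (10, 90))
        assert (curves["p90"] >= curves["p10"] - 1e-12).all()
        assert (curves["p90"].diff().dropna() >= -1e-12).all()  # cumulative incidence

    def test_zero_coefficient_curves_coincide(self, survival_cohort):
        df, _ = survival_cohort
        df = df.copy()
        rng = np.random.default_rng(5)
        df["noise"] = rng.normal(size=len(df))
        fit = fit_cox(df, ["z_instability", "noise"], penalizer_grid=(0.0,),
                      k_folds=None, check_ph=False)
        fit.model.params_["noise"] = 0.0  # force an exactly-null coefficient
        curves = partial_effect_curves(fit, "noise", (10, 90))
        assert np.allclose(curves["p10"], curves["p90"], atol=1e-12)

    def test_weeks_before_first_event_have_zero_incidence(self, survival_cohort):
        fit = self._fit(survival_cohort)
        curves = partial_effect_curves(fit, "z_instability", times=np.array([0.0, 10.0]))
        assert np.allclose(curves.values, 0.0)

    def test_percentile_validation(self, survival_cohort):
        fit = self._fit(survival_cohort)
        with pytest.raises(ParameterError):
            partial_effect_curves(fit, "z_instability", (0, 90))
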