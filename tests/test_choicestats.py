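"""Link functions, exact binomial inference, GLMM, model selection, contrasts."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numfish.choicestats import (
    backward_select,
    build_design,
    classify_g,
    congruency_analysis,
    exact_binomial,
    fit_binomial_glmm,
    inv_logit,
    logit,
    t_from_summary,
    tukey_contrasts,
    validate_choice_table,
)
from conftest import make_bernoulli_table


class TestLinks:
    @pytest.mark.parametrize(
        "log_odds,natural",
        [
            (1.510, 0.82),
            (0.90, 0.71),
            (1.47, 0.81),
            (1.03, 0.74),
            (1.12, 0.75),
            (0.84, 0.70),
            (0.0, 0.5),
        ],
    )
    def test_natural_unit_conversions(self, log_odds, natural):
        assert round(inv_logit(log_odds), 2) == natural

    @settings(max_examples=200, deadline=None)
    @given(st.floats(-10, 10))
    def test_round_trip(self, x):
        assert logit(inv_logit(x)) == pytest.approx(x, abs=1e-9)

    def test_logit_domain(self):
        with pytest.raises(ValueError):
            logit(0.0)
        with pytest.raises(ValueError):
            logit(1.0)


class TestExactBinomial:
    def test_pvalues_match_bruteforce_pmf_summation(self):
        """Two-sided min-likelihood p equals direct PMF enumeration, n <= 50."""
        from math import comb

        def brute_p(k, n):
            pmf = [comb(n, i) * 0.5**n for i in range(n + 1)]
            return min(1.0, sum(q for q in pmf if q <= pmf[k] * (1 + 1e-12)))

        for n in range(1, 51):
            for k in range(0, n + 1, max(1, n // 7)):
                assert exact_binomial(k, n).p_value == pytest.approx(
                    brute_p(k, n), rel=1e-9
                ), (k, n)

    def test_effect_sizes_from_reported_proportions(self):
        # 81.9% of 1000 trials: g rounds to 0.32, large
        s = exact_binomial(819, 1000)
        assert round(s.cohens_g, 2) == 0.32 and s.g_band == "large"
        # 74.3%: g rounds to 0.24, medium
        s = exact_binomial(743, 1000)
        assert round(s.cohens_g, 2) == 0.24 and s.g_band == "medium"

    def test_chance_performance(self):
        s = exact_binomial(24, 48)
        assert s.cohens_g == 0.0
        assert s.g_band == "negligible"
        assert s.p_value == pytest.approx(1.0)

    def test_ci_is_clopper_pearson(self):
        # classical CP interval brackets the estimate
        s = exact_binomial(36, 48)
        assert s.ci_low <= s.p_hat <= s.ci_high
        # CP for k=n has upper bound exactly 1
        assert exact_binomial(10, 10).ci_high == 1.0


class TestClassifyG:
    @pytest.mark.parametrize(
        "g,band",
        [
            (0.0, "negligible"),
            (0.32, "large"),
            (0.255, "large"),  # prints as 0.25 but bands as large unrounded
            (0.25, "medium"),
            (0.12, "small"),
            (0.06, "negligible"),  # gap region, closer to negligible
            (0.09, "small"),  # gap region, closer to small
            (0.16, "small"),
            (0.19, "medium"),
            (-0.3, "large"),  # banding on |g|
        ],
    )
    def test_bands(self, g, band):
        assert classify_g(g) == band

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_g(0.6)


class TestTFromSummary:
    def test_reported_training_duration_comparison(self):
        t, df, p = t_from_summary(451.25, 106.77, 4, 413.25, 73.14, 4)
        assert round(t, 3) == 0.294
        assert df == 6
        assert round(p, 3) == 0.779

    def test_equal_means(self):
        t, df, p = t_from_summary(5.0, 1.0, 4, 5.0, 2.0, 4)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_pooled_equals_welch_at_equal_n(self, rng):
        m1, m2 = rng.normal(size=2)
        s1, s2 = rng.uniform(0.5, 2.0, 2)
        t_pooled, _, _ = t_from_summary(m1, s1, 6, m2, s2, 6)
        welch_t = (m1 - m2) / math.sqrt(s1**2 + s2**2)
        assert t_pooled == pytest.approx(welch_t, abs=1e-12)


class TestGLMM:
    def test_zero_variance_reduces_to_plain_glm(self, rng):
        import statsmodels.api as sm

        df = make_bernoulli_table(6, 150, 0.75, rng)
        fit = fit_binomial_glmm(df, ["geometry_control"])
        assert fit.random_intercept_variance < 1e-8
        X, names, _ = build_design(df, [("geometry_control",)])
        glm = sm.GLM(
            df["chose_target"].to_numpy(float), X, family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(fit.fixed_effects, glm.params, atol=1e-6)
        np.testing.assert_allclose(fit.fixed_se, glm.bse, atol=1e-6)
        assert fit.log_likelihood == pytest.approx(glm.llf, abs=1e-6)

    def test_intercept_only_zero_variance_is_pooled_logit(self, rng):
        df = make_bernoulli_table(5, 100, 0.7, rng)
        fit = fit_binomial_glmm(df, [], force_zero_variance=True)
        pooled = df["chose_target"].mean()
        assert fit.fixed_effects[0] == pytest.approx(logit(pooled), abs=1e-8)

    def test_bic_exceeds_aic_for_moderate_n(self, rng):
        df = make_bernoulli_table(4, 60, 0.7, rng)
        fit = fit_binomial_glmm(df, ["geometry_control"])
        assert fit.n_obs > math.e**2
        assert fit.bic > fit.aic

    def test_positive_variance_recovered(self, rng):
        df = make_bernoulli_table(12, 250, 0.73, rng, fish_sd=math.sqrt(0.5))
        fit = fit_binomial_glmm(df, [])
        assert 0.1 < fit.random_intercept_variance < 1.5

    def test_laplace_close_to_adaptive_quadrature(self, rng):
        df = make_bernoulli_table(8, 120, 0.7, rng, fish_sd=0.7)
        lap = fit_binomial_glmm(df, [])
        agq = fit_binomial_glmm(df, [], method="agq", agq_nodes=15)
        np.testing.assert_allclose(lap.fixed_effects, agq.fixed_effects, atol=0.02)
        assert abs(lap.log_likelihood - agq.log_likelihood) < 0.5

    def test_matches_lme4_glmer(self, rng, tmp_path):
        """Independent oracle: lme4's Laplace ML fit on the same data."""
        df = make_bernoulli_table(8, 120, 0.72, rng, fish_sd=0.8)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(chose_target ~ geometry_control + (1|fish_id),
                       data=d, family=binomial)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vals = [float(v) for v in out.stdout.strip().split("\n")]
        fit = fit_binomial_glmm(df, ["geometry_control"])
        np.testing.assert_allclose(fit.fixed_effects, vals[:3], atol=2e-3)
        assert fit.random_intercept_variance == pytest.approx(
            vals[3] ** 2, abs=5e-3
        )
        assert fit.log_likelihood == pytest.approx(vals[4], abs=1e-3)

    def test_needs_two_groups(self, rng):
        df = make_bernoulli_table(1, 50, 0.7, rng)
        with pytest.raises(ValueError):
            fit_binomial_glmm(df, [])


class TestBackwardSelect:
    def test_strong_effect_retained(self, rng):
        # delta log-odds ~ 1.5 between geometry levels
        df = make_bernoulli_table(
            6, 340, {"radius_fixed": 0.5, "area_eq": 0.82, "perim_eq": 0.5}, rng
        )
        fit, trace = backward_select(df, ["geometry_control", "spatial_control"])
        assert ("geometry_control",) in trace[-1]["terms"]

    def test_null_drops_everything(self, rng):
        df = make_bernoulli_table(6, 150, 0.7, rng)
        fit, trace = backward_select(
            df,
            ["geometry_control", "spatial_control",
             ("geometry_control", "spatial_control")],
        )
        assert trace[-1]["terms"] == []
        assert len(fit.fixed_effects) == 1

    def test_interaction_removed_before_main_effects(self, rng):
        df = make_bernoulli_table(6, 150, 0.7, rng)
        _, trace = backward_select(
            df,
            ["geometry_control", "spatial_control",
             ("geometry_control", "spatial_control")],
        )
        removed = [step["removed"] for step in trace[1:]]
        if removed:
            assert removed[0] == ("geometry_control", "spatial_control")

    def test_single_candidate_returned_unchanged(self, rng):
        df = make_bernoulli_table(
            6, 340, {"radius_fixed": 0.5, "area_eq": 0.85, "perim_eq": 0.5}, rng
        )
        fit, trace = backward_select(df, ["geometry_control"])
        assert trace[-1]["terms"] == [("geometry_control",)]

    def test_bad_criterion(self, rng):
        df = make_bernoulli_table(4, 40, 0.6, rng)
        with pytest.raises(ValueError):
            backward_select(df, [], criterion="DIC")


class TestTukeyContrasts:
    def test_two_level_factor_adjusted_equals_unadjusted(self, rng):
        df = make_bernoulli_table(6, 200, 0.7, rng)
        fit = fit_binomial_glmm(df, ["spatial_control"])
        con = tukey_contrasts(fit, "spatial_control")
        assert len(con) == 1
        assert con["p_adjusted"].iloc[0] == pytest.approx(
            con["p_unadjusted"].iloc[0], rel=1e-3
        )

    def test_adjusted_never_smaller_than_unadjusted(self, rng):
        df = make_bernoulli_table(
            6, 160, {"radius_fixed": 0.6, "area_eq": 0.7, "perim_eq": 0.8}, rng
        )
        fit = fit_binomial_glmm(df, ["geometry_control"])
        con = tukey_contrasts(fit, "geometry_control")
        assert len(con) == 3
        assert (con["p_adjusted"] >= con["p_unadjusted"] - 1e-12).all()

    def test_null_p_values_roughly_uniform(self, rng):
        """Median adjusted p over null simulations for 2 identical groups ~ 0.5."""
        ps = []
        for s in range(40):
            df = make_bernoulli_table(4, 120, 0.7, np.random.default_rng(1000 + s))
            fit = fit_binomial_glmm(df, ["spatial_control"])
            ps.append(tukey_contrasts(fit, "spatial_control")["p_adjusted"].iloc[0])
        assert 0.3 < np.median(ps) < 0.7

    def test_unknown_factor(self, rng):
        df = make_bernoulli_table(4, 60, 0.7, rng)
        fit = fit_binomial_glmm(df, [])
        with pytest.raises(ValueError):
            tukey_contrasts(fit, "geometry_control")


class TestCongruencyAnalysis:
    def _table_with_levels(self, rng, p_by_level):
        rows = []
        for f in range(6):
            for t in range(240):
                lev = int(rng.integers(1, 4))
                rows.append(
                    {
                        "fish_id": f"f{f}",
                        "congruency_level": lev,
                        "chose_target": int(rng.random() < p_by_level[lev]),
                        "responded": 1,
                    }
                )
        return pd.DataFrame(rows)

    def test_flat_accuracy_no_significant_contrasts(self, rng):
        table = self._table_with_levels(rng, {1: 0.74, 2: 0.74, 3: 0.74})
        result = congruency_analysis(table)
        assert (result["contrasts"]["p_adjusted"] > 0.05).all()

    def test_graded_accuracy_detected(self, rng):
        table = self._table_with_levels(rng, {1: 0.60, 2: 0.75, 3: 0.90})
        result = congruency_analysis(table)
        assert (result["contrasts"]["p_adjusted"] < 0.05).any()
        est = result["level_estimates"]
        assert (est["ci_low"] <= est["log_odds"]).all()
        assert (est["log_odds"] <= est["ci_high"]).all()

    def test_missing_level_warns_and_proceeds(self, rng):
        table = self._table_with_levels(rng, {1: 0.7, 2: 0.7, 3: 0.7})
        table = table[table["congruency_level"] != 3]
        with pytest.warns(UserWarning):
            result = congruency_analysis(table)
        assert len(result["contrasts"]) == 1


class TestChoiceTableSchema:
    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            validate_choice_table(pd.DataFrame({"fish_id": ["a"]}))

    def test_valid_table_passes(self, rng):
        from numfish.synthdata import simulate_study

        table = simulate_study("exp2", seed=0)
        assert validate_choice_table(table) is table
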