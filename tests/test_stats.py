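"""Statistical engine against enumeration, closed-form, and hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from conftest import exact_ranksum_p, km_product_limit, one_sample_t_p

import cavquant as cq
from cavquant.stats import cox_fit, km_fit


class TestRankSum:
    def test_identical_groups_p_one(self):
        res = cq.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_small_sample_exact(self):
        res = cq.wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "wilcoxon_rank_sum_exact"
        assert res.p_value == pytest.approx(2 / 6)

    @pytest.mark.parametrize("n,m", [(2, 2), (3, 5), (4, 4), (5, 3), (8, 8), (1, 6)])
    def test_exact_matches_enumeration_oracle(self, n, m):
        """Exact small-sample p equals brute-force enumeration of rank splits."""
        rng = np.random.default_rng(n * 10 + m)
        for _ in range(3):
            pooled = rng.permutation(np.arange(1.0, n + m + 1))  # tie-free
            x, y = pooled[:n], pooled[n:]
            res = cq.wilcoxon_rank_sum(x, y)
            assert res.p_value == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(1.0, 1.0, size=15)
        assert cq.wilcoxon_rank_sum(x, y).p_value == pytest.approx(
            cq.wilcoxon_rank_sum(y, x).p_value
        )

    def test_monotone_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=10), rng.normal(size=10)
        p1 = cq.wilcoxon_rank_sum(x, y).p_value
        p2 = cq.wilcoxon_rank_sum(np.exp(x), np.exp(y)).p_value
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cq.wilcoxon_rank_sum([1.0], [np.nan])


class TestKruskalWallis:
    def test_identical_groups_null(self):
        res = cq.kruskal_wallis([[1, 2], [1, 2], [1, 2]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_h(self):
        """H for {1,2},{3,4},{5,6} from the rank-variance formula."""
        # ranks 1..6, group mean ranks 1.5, 3.5, 5.5:
        # H = 12/(6*7) * 2 * [(1.5-3.5)^2 + 0 + (5.5-3.5)^2] = 32/7
        res = cq.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32 / 7)

    def test_two_groups_redirected(self):
        with pytest.raises(ValueError, match="wilcoxon"):
            cq.kruskal_wallis([[1, 2], [3, 4]])

    def test_all_constant_degenerate(self):
        res = cq.kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert (res.statistic, res.p_value) == (0.0, 1.0)


class TestMeanDifference:
    def test_zero_deltas(self):
        res = cq.mean_difference_test([0.0, 0.0, 0.0], paired=True)
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_paired_matches_closed_form(self):
        deltas = [-1.0, -2.0, -3.0]
        res = cq.mean_difference_test(deltas, paired=True)
        assert res.p_value == pytest.approx(one_sample_t_p(deltas))

    def test_zero_variance_nonzero_mean_flagged(self):
        with pytest.warns(UserWarning):
            res = cq.mean_difference_test([2.0, 2.0, 2.0], paired=True)
        assert np.isnan(res.p_value)

    def test_anova_equal_groups_f_zero(self):
        res = cq.mean_difference_test([1.0, 2.0], [1.0, 2.0], [1.0, 2.0])
        assert res.method == "anova"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_sample_matches_scipy_convention(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=10), rng.normal(0.5, 1, size=12)
        res = cq.mean_difference_test(x, y)
        from scipy.stats import ttest_ind

        stat, p = ttest_ind(x, y)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = cq.pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(5.0)
        assert cq.pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 2.0, 5.0, 4.0])
        r_oracle = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        res = cq.pearson_correlation(x, y)
        assert res.r == pytest.approx(r_oracle)
        assert res.r2 == pytest.approx(r_oracle**2)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            res = cq.pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.r)


class TestKaplanMeier:
    def test_uncensored_product_limit_steps(self):
        times = np.arange(1.0, 11.0)
        fit = km_fit(times, np.ones(10, dtype=int))
        curve = fit.km_curves["all"]
        surv_at_event = curve[curve["t"] > 0]["S"].to_numpy()
        np.testing.assert_allclose(surv_at_event, 1.0 - np.arange(1, 11) / 10.0, atol=1e-12)
        assert fit.medians["all"] == pytest.approx(5.0)

    def test_censored_curve_matches_hand_oracle(self):
        times = [1.0, 2.0, 2.0, 3.0, 4.0]
        events = [1, 0, 1, 1, 0]
        curve, median = km_product_limit(times, events)
        fit = km_fit(times, events)
        km = fit.km_curves["all"].set_index("t")["S"]
        for t, s in curve:
            assert km.loc[t] == pytest.approx(s)
        assert fit.medians["all"] == pytest.approx(median)

    def test_identical_groups_logrank_null(self):
        times = np.tile(np.arange(1.0, 11.0), 2)
        events = np.ones(20, dtype=int)
        groups = np.repeat(["a", "b"], 10)
        fit = km_fit(times, events, groups)
        assert fit.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert fit.logrank_p == pytest.approx(1.0)

    def test_all_censored_median_not_reached(self):
        fit = km_fit([5.0, 6.0, 7.0], [0, 0, 0])
        assert fit.medians["all"] is None

    def test_exponential_groups_separate(self):
        rng = np.random.default_rng(3)
        n = 500
        t0 = rng.exponential(1.0, n)
        t1 = rng.exponential(np.exp(-0.7), n)
        times = np.concatenate([t0, t1])
        events = np.ones(2 * n, dtype=int)
        groups = np.repeat(["slow", "fast"], n)
        fit = km_fit(times, events, groups)
        assert fit.logrank_p < 1e-6
        assert fit.medians["fast"] < fit.medians["slow"]


class TestCox:
    def test_closed_form_partial_likelihood(self):
        """4 subjects, 2 events, binary covariate: the partial-likelihood score
        equation reduces to 2 - u^2 = 0 with u = exp(beta), so beta = ln(sqrt 2)."""
        df = pd.DataFrame(
            {
                "t": [1.0, 2.0, 3.0, 4.0],
                "e": [1, 1, 0, 0],
                "x": [1.0, 0.0, 1.0, 0.0],
            }
        )
        fit = cox_fit(df, "t", "e", ["x"])
        assert fit.converged
        assert fit.hr_table.loc["x", "coef"] == pytest.approx(np.log(np.sqrt(2.0)), abs=1e-5)

    def test_duplicated_data_same_hr_narrower_ci(self):
        rng = np.random.default_rng(4)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        df = pd.DataFrame({"t": t, "e": 1, "x": x})
        single = cox_fit(df, "t", "e", ["x"])
        double = cox_fit(pd.concat([df, df], ignore_index=True), "t", "e", ["x"])
        # duplication creates ties; Efron's tie correction perturbs the point
        # estimate slightly (it would be exactly invariant under Breslow)
        assert double.hr_table.loc["x", "hr"] == pytest.approx(single.hr_table.loc["x", "hr"], rel=1e-2)
        ci_single = single.hr_table.loc["x", "ci_high"] - single.hr_table.loc["x", "ci_low"]
        ci_double = double.hr_table.loc["x", "ci_high"] - double.hr_table.loc["x", "ci_low"]
        assert ci_double < ci_single

    def test_separation_flagged_not_raised(self):
        # covariate perfectly orders the events: monotone likelihood
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0, 4.0], "e": [1, 1, 0, 0], "x": [5.0, 4.0, 0.0, 0.0]})
        with pytest.warns(UserWarning):
            fit = cox_fit(df, "t", "e", ["x"])
        assert not fit.converged


class TestLogistic:
    def test_balanced_table_or_one(self):
        y = np.repeat([1, 0, 1, 0], 10)
        x = np.repeat([1, 1, 0, 0], 10)
        fit = cq.logistic_fit(y, pd.DataFrame({"x": x}))
        assert fit.or_table.loc["x", "odds_ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_cross_product_odds_ratio(self):
        """2x2 table {a=20, b=10, c=10, d=20}: MLE odds ratio is ad/bc = 4."""
        y = np.concatenate([np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)])
        x = np.concatenate([np.ones(30), np.zeros(30)])
        fit = cq.logistic_fit(y, pd.DataFrame({"x": x}))
        assert fit.or_table.loc["x", "odds_ratio"] == pytest.approx(4.0, rel=1e-4)

    def test_separation_flagged(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        with pytest.warns(UserWarning):
            fit = cq.logistic_fit(y, pd.DataFrame({"x": x}))
        assert not fit.converged

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cq.logistic_fit(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))
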