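import itertools

import numpy as np
import pytest
from scipy import optimize, stats

from immunoscore import (
    chi2_importance,
    cox_fit,
    harrell_c,
    km_estimate,
    likelihood_ratio_test,
    logrank_test,
    logrank_trend_test,
    rate_at,
    rmst_compare,
    wald_summary,
)
from immunoscore.survival import _cox_quantities


def random_survival(n, seed, cens_scale=40.0, event_scale=30.0):
    rng = np.random.default_rng(seed)
    t_event = rng.exponential(event_scale, n)
    t_cens = rng.exponential(cens_scale, n)
    t = np.minimum(t_event, t_cens).round(3) + 0.1
    e = t_event <= t_cens
    return t, e


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        curve = km_estimate([3.0, 7.0, 9.0], [False, False, False])
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_hand_product_limit(self):
        # 3 subjects: event at 5, censored at 10, event at 15
        curve = km_estimate([5.0, 10.0, 15.0], [True, False, True])
        np.testing.assert_allclose(curve.event_times, [5.0, 15.0])
        np.testing.assert_allclose(curve.survival, [2.0 / 3.0, 0.0])

    def test_uncensored_equals_empirical_survivor(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 60).round(1) + 0.1
        curve = km_estimate(t, np.ones(60, bool))
        for q in [0.5, 3.0, 8.0, 20.0]:
            assert curve.survival_at(q) == pytest.approx(np.mean(t > q))

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        t, e = random_survival(120, seed=7)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        curve = km_estimate(t, e)
        for q in [1.0, 10.0, 30.0, 70.0]:
            assert curve.survival_at(q) == pytest.approx(
                float(kmf.predict(q)), abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty|least one"):
            km_estimate([], [])


class TestRateAt:
    def test_time_zero_is_100_percent(self):
        curve = km_estimate([5.0], [True])
        assert rate_at(curve, 0.0)["rate"] == 100.0

    def test_single_event_among_two(self):
        curve = km_estimate([36.0, 80.0], [True, False])
        assert rate_at(curve, 36.0)["rate"] == pytest.approx(50.0)

    def test_ci_bounded_even_near_one(self):
        t, e = random_survival(50, seed=3, event_scale=500.0)
        curve = km_estimate(t, e)
        for q in np.linspace(0.5, float(t.max()), 20):
            lo, hi = rate_at(curve, q)["ci_95"]
            assert 0.0 <= lo <= hi <= 100.0

    def test_extrapolation_flagged(self):
        curve = km_estimate([5.0, 10.0], [True, False])
        assert rate_at(curve, 11.0)["extrapolated"]
        assert not rate_at(curve, 10.0)["extrapolated"]


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t, e = random_survival(30, seed=5)
        res = logrank_test([(t, e), (t.copy(), e.copy())])
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_exhaustive_permutation_oracle_small_n(self):
        # n=8, two groups of 4: the permutation distribution of the statistic
        # over all 70 label assignments gives the exact p-value
        t = np.array([2.0, 5.0, 7.0, 11.0, 13.0, 17.0, 23.0, 29.0])
        e = np.array([True, True, False, True, True, True, False, True])
        obs = logrank_test([(t[:4], e[:4]), (t[4:], e[4:])]).statistic
        stats_perm = []
        for idx in itertools.combinations(range(8), 4):
            a = np.array(idx)
            b = np.array([i for i in range(8) if i not in idx])
            stats_perm.append(logrank_test([(t[a], e[a]), (t[b], e[b])]).statistic)
        p_perm = np.mean(np.array(stats_perm) >= obs - 1e-12)
        p_chi2 = logrank_test([(t[:4], e[:4]), (t[4:], e[4:])]).p_value
        assert p_chi2 == pytest.approx(p_perm, abs=0.15)

    def test_collapsing_three_groups_to_two(self):
        t, e = random_survival(60, seed=9)
        g = np.random.default_rng(1).integers(0, 3, 60)
        three = logrank_test([(t[g == i], e[g == i]) for i in range(3)])
        # merging groups 1 and 2 into one label reduces to the 2-group test
        merged = g.copy()
        merged[merged == 2] = 1
        two = logrank_test([(t[merged == i], e[merged == i]) for i in range(2)])
        direct = logrank_test([(t[g == 0], e[g == 0]),
                               (np.concatenate([t[g == 1], t[g == 2]]),
                                np.concatenate([e[g == 1], e[g == 2]]))])
        assert two.statistic == pytest.approx(direct.statistic, abs=1e-12)
        assert three.df == 2 and two.df == 1

    def test_matches_lifelines_multigroup(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        t, e = random_survival(90, seed=13)
        g = np.random.default_rng(2).integers(0, 3, 90)
        res = logrank_test([(t[g == i], e[g == i]) for i in range(3)])
        ref = lifelines_stats.multivariate_logrank_test(t, g, e)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([([1.0], [True]), ([], [])])


class TestTrendTest:
    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError, match="3 ordered groups"):
            logrank_trend_test([([1.0], [True]), ([2.0], [True])])

    def test_invariant_to_reversing_score_direction(self):
        groups = [random_survival(25, seed=s, event_scale=20 + 10 * s)
                  for s in range(3)]
        fwd = logrank_trend_test(groups)
        rev = logrank_trend_test(groups[::-1])
        assert fwd.statistic == pytest.approx(rev.statistic, rel=1e-9)
        assert fwd.df == 1

    def test_monotone_hazard_yields_larger_statistic_than_scrambled(self):
        rng = np.random.default_rng(11)
        groups = []
        for k, scale in enumerate([10.0, 25.0, 60.0]):
            t = rng.exponential(scale, 60).round(3) + 0.1
            groups.append((t, np.ones(60, bool)))
        ordered = logrank_trend_test(groups).statistic
        scrambled = logrank_trend_test([groups[1], groups[0], groups[2]]).statistic
        assert ordered > scrambled


def _plain_partial_loglik(beta, x, t, e):
    """Test-local tie-free partial likelihood for the grid-search oracle."""
    ll = 0.0
    for i in np.nonzero(e)[0]:
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_single_covariate_matches_grid_search_oracle(self):
        rng = np.random.default_rng(21)
        n = 40
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(30 * np.exp(-0.8 * x)).round(5) + 0.01
        e = np.ones(n, bool)
        assert np.unique(t).size == n  # tie-free by construction
        fit = cox_fit({"x": x}, t, e)
        res = optimize.minimize_scalar(
            lambda b: -_plain_partial_loglik(b, x, t, e),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-8})
        assert fit.coefficients["x"] == pytest.approx(res.x, abs=1e-4)
        assert fit.converged

    def test_one_stratum_equals_unstratified(self):
        t, e = random_survival(60, seed=31)
        x = np.random.default_rng(4).normal(size=60)
        a = cox_fit({"x": x}, t, e)
        b = cox_fit({"x": x}, t, e, strata=np.zeros(60, int))
        assert a.coefficients == pytest.approx(b.coefficients)
        assert a.loglik_fitted == pytest.approx(b.loglik_fitted)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(41)
        t = rng.permutation(np.arange(1.0, 61.0))
        e = rng.random(60) < 0.6
        x = rng.normal(size=60)
        ef = cox_fit({"x": x}, t, e, ties_method="efron")
        br = cox_fit({"x": x}, t, e, ties_method="breslow")
        assert ef.coefficients["x"] == pytest.approx(br.coefficients["x"], abs=1e-9)
        assert ef.loglik_fitted == pytest.approx(br.loglik_fitted, abs=1e-9)

    def test_coefficient_invariant_under_time_rescaling(self):
        t, e = random_survival(80, seed=51)
        x = np.random.default_rng(6).normal(size=80)
        a = cox_fit({"x": x}, t, e)
        b = cox_fit({"x": x}, 3.7 * t, e)
        assert a.coefficients["x"] == pytest.approx(b.coefficients["x"], abs=1e-7)

    def test_matches_lifelines_with_ties_and_strata(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(61)
        n = 150
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n).astype(float)
        strata = rng.integers(0, 3, n)
        t = np.ceil(rng.exponential(20 * np.exp(-0.5 * x1 - 0.3 * x2)))  # monthly ties
        e = rng.random(n) < 0.7
        t = np.maximum(t, 1.0)
        fit = cox_fit({"x1": x1, "x2": x2}, t, e, strata=strata)
        df = pd.DataFrame({"t": t, "e": e.astype(int), "x1": x1, "x2": x2, "s": strata})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e", strata=["s"])
        assert fit.coefficients["x1"] == pytest.approx(cph.params_["x1"], abs=1e-5)
        assert fit.coefficients["x2"] == pytest.approx(cph.params_["x2"], abs=1e-5)
        assert fit.loglik_fitted == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_logrank_equals_cox_score_test(self):
        # two-group log-rank chi-square == squared Cox score z on the group
        # indicator (tie-free data, Breslow)
        rng = np.random.default_rng(71)
        t = rng.permutation(np.arange(1.0, 51.0))
        e = rng.random(50) < 0.7
        g = rng.integers(0, 2, 50)
        lr = logrank_test([(t[g == 0], e[g == 0]), (t[g == 1], e[g == 1])])
        _, grad, info = _cox_quantities(np.zeros(1), g.reshape(-1, 1).astype(float),
                                        t, e, np.zeros(50, int), "breslow")
        score_chi2 = float(grad[0] ** 2 / info[0, 0])
        assert lr.statistic == pytest.approx(score_chi2, abs=1e-6)

    def test_zero_event_level_reported_infinite(self):
        # the covariate level with all the events has a diverging hazard
        # ratio: reported as inf with p = NA, not raised
        t = np.array([5.0, 8.0, 12.0, 20.0, 25.0, 30.0, 40.0, 50.0])
        e = np.array([True, True, True, True, False, False, False, False])
        x = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        fit = cox_fit({"x": x}, t, e)
        assert not fit.converged
        assert "x" in fit.infinite_terms
        w = wald_summary(fit, "x")
        assert w["hr"] == float("inf")
        assert w["ci_95"] == (0.0, float("inf"))
        assert np.isnan(w["p_value"])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_fit({"x": [0.0, 1.0]}, [1.0, 2.0], [False, False])


class TestWaldSummary:
    def test_closed_form(self):
        from immunoscore import CoxFit
        fit = CoxFit(coefficients={"x": 0.0}, covariance=np.array([[0.25]]),
                     loglik_null=0.0, loglik_fitted=0.0, strata_labels=[0],
                     ties_method="efron", converged=True, n=10, n_events=5)
        w = wald_summary(fit, "x")
        assert w["hr"] == pytest.approx(1.0)
        assert w["ci_95"][0] == pytest.approx(0.3753, abs=1e-3)
        assert w["ci_95"][1] == pytest.approx(2.6645, abs=1e-3)
        assert w["p_value"] == pytest.approx(1.0)

    def test_symmetric_bounds_on_log_scale(self):
        from immunoscore import CoxFit
        fit = CoxFit(coefficients={"x": np.log(2.0)}, covariance=np.array([[0.04]]),
                     loglik_null=0.0, loglik_fitted=0.0, strata_labels=[0],
                     ties_method="efron", converged=True, n=10, n_events=5)
        w = wald_summary(fit, "x")
        lo, hi = w["ci_95"]
        assert np.log(lo) + np.log(hi) == pytest.approx(2 * np.log(2.0), abs=1e-12)


class TestLRT:
    def test_same_model_statistic_zero(self):
        t, e = random_survival(50, seed=81)
        x = np.random.default_rng(8).normal(size=50)
        fit = cox_fit({"x": x}, t, e)
        res = likelihood_ratio_test(fit, fit)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_adding_covariate_never_decreases_loglik(self):
        t, e = random_survival(80, seed=91)
        rng = np.random.default_rng(9)
        x, z = rng.normal(size=80), rng.normal(size=80)
        nested = cox_fit({"x": x}, t, e)
        full = cox_fit({"x": x, "z": z}, t, e)
        assert full.loglik_fitted >= nested.loglik_fitted - 1e-8
        res = likelihood_ratio_test(nested, full)
        assert res.df == 1 and 0.0 <= res.p_value <= 1.0

    def test_non_nested_rejected(self):
        t, e = random_survival(40, seed=95)
        rng = np.random.default_rng(10)
        a = cox_fit({"x": rng.normal(size=40)}, t, e)
        b = cox_fit({"z": rng.normal(size=40)}, t, e)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(a, b)


class TestHarrellC:
    def test_constant_score_is_half(self):
        t, e = random_survival(40, seed=101)
        res = harrell_c(np.zeros(40), t, e)
        assert res.c_index == pytest.approx(0.5)

    def test_perfect_ranking_uncensored(self):
        rng = np.random.default_rng(12)
        t = rng.permutation(np.arange(1.0, 31.0))
        res = harrell_c(-t, t, np.ones(30, bool))
        assert res.c_index == 1.0
        assert res.n_comparable_pairs == 30 * 29 // 2

    def test_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(14)
        n = 30
        score = rng.normal(size=n)
        t = rng.permutation(np.arange(1.0, n + 1.0))
        e = rng.random(n) < 0.6
        conc = pairs = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if e[i] and (t[i] < t[j] or (t[i] == t[j] and not e[j])):
                    pairs += 1
                    conc += 1.0 if score[i] > score[j] else (0.5 if score[i] == score[j] else 0.0)
        res = harrell_c(score, t, e)
        assert res.n_comparable_pairs == pairs
        assert res.c_index == pytest.approx(conc / pairs)

    def test_matches_lifelines_concordance(self):
        lifelines_utils = pytest.importorskip("lifelines.utils")
        rng = np.random.default_rng(15)
        n = 80
        score = rng.normal(size=n)
        t = rng.permutation(np.arange(1.0, n + 1.0))  # distinct times
        e = rng.random(n) < 0.5
        res = harrell_c(score, t, e)
        ref = lifelines_utils.concordance_index(t, -score, e)
        assert res.c_index == pytest.approx(ref, abs=1e-12)

    def test_bootstrap_ci_deterministic_under_seed(self):
        t, e = random_survival(50, seed=105)
        s = np.random.default_rng(16).normal(size=50)
        a = harrell_c(s, t, e, seed=9)
        b = harrell_c(s, t, e, seed=9)
        assert a.ci_95 == b.ci_95


class TestRMST:
    def test_no_events_gives_tau(self):
        res = rmst_compare(([50.0, 60.0], [False, False]),
                           ([10.0, 20.0, 30.0], [True, True, False]), tau=30.0)
        assert res.rmst_per_group[0] == pytest.approx(30.0)

    def test_identical_groups_difference_zero(self):
        t, e = random_survival(40, seed=111)
        res = rmst_compare((t, e), (t.copy(), e.copy()))
        assert res.difference == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_uncensored_equals_mean_truncated_time(self):
        rng = np.random.default_rng(17)
        ta = rng.exponential(20, 50).round(3) + 0.1
        tb = rng.exponential(35, 50).round(3) + 0.1
        tau = 25.0
        res = rmst_compare((ta, np.ones(50, bool)), (tb, np.ones(50, bool)), tau=tau)
        assert res.rmst_per_group[0] == pytest.approx(np.mean(np.minimum(ta, tau)))
        assert res.rmst_per_group[1] == pytest.approx(np.mean(np.minimum(tb, tau)))
        assert res.difference == pytest.approx(
            np.mean(np.minimum(ta, tau)) - np.mean(np.minimum(tb, tau)))

    def test_matches_lifelines_rmst(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.utils import restricted_mean_survival_time

        t, e = random_survival(70, seed=115)
        tau = 30.0
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        ref = restricted_mean_survival_time(kmf, t=tau)
        res = rmst_compare((t, e), (t.copy(), e.copy()), tau=tau)
        assert res.rmst_per_group[0] == pytest.approx(float(ref), abs=1e-9)

    def test_tau_beyond_follow_up_rejected_naming_group(self):
        with pytest.raises(ValueError, match="group b"):
            rmst_compare(([50.0], [False]), ([10.0], [False]), tau=20.0)


class TestImportance:
    def test_single_variable_proportion_one(self):
        t, e = random_survival(60, seed=121)
        x = np.random.default_rng(18).normal(size=60)
        fit = cox_fit({"x": x}, t, e)
        res = chi2_importance(fit)
        assert res.proportion["x"] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(19)
        n = 120
        x = rng.normal(size=n)
        z = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(20 * np.exp(-0.5 * x - 0.5 * z)).round(4) + 0.01
        fit = cox_fit({"x": x, "z": z}, t, np.ones(n, bool))
        res = chi2_importance(fit)
        assert sum(res.proportion.values()) == pytest.approx(1.0, abs=1e-9)

    def test_balanced_equal_effects_split_evenly(self):
        rng = np.random.default_rng(23)
        n = 4000
        x = rng.integers(0, 2, n).astype(float)
        z = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(20 * np.exp(-0.7 * x - 0.7 * z)) + 1e-4
        fit = cox_fit({"x": x, "z": z}, t, np.ones(n, bool))
        res = chi2_importance(fit)
        assert res.proportion["x"] == pytest.approx(0.5, abs=0.12)
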