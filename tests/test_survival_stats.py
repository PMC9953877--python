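"""Kaplan-Meier, rank tests, and Cox regression against independent oracles.

Hand-enumerated risk sets and lifelines (an independent implementation)
check the estimators; simulations check parameter recovery.
"""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.statistics import multivariate_logrank_test
from scipy.optimize import minimize_scalar

from bcsurv.survival_stats import (
    StepwiseSpec,
    SurvivalRecord,
    cox_fit,
    gehan_wilcoxon_test,
    km_estimate,
    km_median,
    logrank_test,
    stepwise_cox,
    univariate_screen,
)


def _sim_two_groups(rng, n, log_hr, censor_scale=None):
    """Exponential survival, binary covariate with the given log-HR."""
    x = rng.integers(0, 2, size=n)
    t = rng.exponential(1.0 / np.exp(log_hr * x))
    if censor_scale is None:
        return t, np.ones(n, bool), x
    c = rng.exponential(censor_scale, size=n)
    return np.minimum(t, c), t <= c, x


class TestKaplanMeier:
    def test_no_censoring_is_empirical_survival(self):
        curve = km_estimate((np.arange(1.0, 6.0), np.ones(5, bool)))
        assert np.allclose(curve.survival, [0.8, 0.6, 0.4, 0.2, 0.0])

    def test_all_censored_flat_at_one(self):
        curve = km_estimate((np.array([3.0, 5.0, 8.0]), np.zeros(3, bool)))
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_hand_product_with_tied_events_and_censoring(self):
        # {6,6,7+,9}: S(6) = (4-2)/4 = 0.5; at t=9 the risk set is the one
        # remaining subject, so S(9) = 0.5 * (1 - 1/1) = 0 (lifelines agrees)
        curve = km_estimate((np.array([6.0, 6.0, 7.0, 9.0]),
                             np.array([1, 1, 0, 1], bool)))
        assert np.allclose(curve.event_times, [6.0, 9.0])
        assert np.allclose(curve.survival, [0.5, 0.0])
        assert np.array_equal(curve.at_risk, [4, 1])

    def test_matches_lifelines_on_random_data(self, rng):
        t = rng.exponential(10.0, 80).round(1) + 0.1
        e = rng.random(80) < 0.7
        curve = km_estimate((t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        for ti, si in zip(curve.event_times, curve.survival):
            assert si == pytest.approx(
                float(kmf.survival_function_at_times(ti).iloc[0]), abs=1e-10)

    def test_greenwood_variance_matches_hand_sum(self):
        t = np.array([2.0, 4.0, 4.0, 6.0, 8.0])
        e = np.array([1, 1, 1, 0, 1], bool)
        curve = km_estimate((t, e))
        # hand: t=2 (n=5,d=1), t=4 (n=4,d=2), t=8 (n=1,d=1)
        s2 = 4 / 5
        s4 = s2 * 2 / 4
        g2 = 1 / (5 * 4)
        g4 = g2 + 2 / (4 * 2)
        assert curve.survival[0] == pytest.approx(s2)
        assert curve.greenwood_var[0] == pytest.approx(s2**2 * g2)
        assert curve.greenwood_var[1] == pytest.approx(s4**2 * g4)

    def test_survival_monotone_nonincreasing(self, rng):
        t = rng.exponential(5.0, 200) + 0.01
        e = rng.random(200) < 0.6
        curve = km_estimate((t, e))
        assert np.all(np.diff(curve.survival) <= 1e-15)
        assert np.all(np.diff(curve.at_risk) < 0)

    def test_median(self):
        assert km_median((np.arange(1.0, 5.0), np.ones(4, bool))) == 2.0
        assert km_median((np.array([5.0]), np.array([0], bool))) == math.inf

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate((np.array([]), np.array([], bool)))

    def test_record_objects_accepted(self):
        recs = [SurvivalRecord("a", 3.0, True), SurvivalRecord("b", 5.0, False)]
        assert km_estimate(recs).event_times.tolist() == [3.0]


class TestRankTests:
    def test_identical_groups_null(self):
        g = (np.array([2.0, 4.0, 6.0]), np.array([1, 1, 0], bool))
        res = logrank_test([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_hand_enumeration_two_groups(self):
        # A: 1(e), 3(e); B: 2(e), 4(c). Risk sets by hand:
        # t=1: n=4, nA=2, d=1, dA=1 -> O-E = 1 - 2/4;  V = (1*3/3)*(2/4)(2/4)
        # t=2: n=3, nA=1, d=1, dA=0 -> O-E = 0 - 1/3;  V = (2/3)(1/3)... d(n-d)/(n-1)=1
        # t=3: n=2, nA=1, d=1, dA=1 -> O-E = 1 - 1/2;  V = (1/2)(1/2)
        oe = (1 - 0.5) + (0 - 1 / 3) + (1 - 0.5)
        var = (0.5 * 0.5) + (1 / 3 * 2 / 3) + (0.5 * 0.5)
        ga = (np.array([1.0, 3.0]), np.array([1, 1], bool))
        gb = (np.array([2.0, 4.0]), np.array([1, 0], bool))
        res = logrank_test([ga, gb])
        assert res.statistic == pytest.approx(oe**2 / var, rel=1e-12)

    def test_matches_lifelines(self, rng):
        t = rng.exponential(8.0, 120) + 0.05
        e = rng.random(120) < 0.7
        g = rng.integers(0, 3, 120)
        groups = [(t[g == k], e[g == k]) for k in range(3)]
        res = logrank_test(groups)
        ref = multivariate_logrank_test(t, g, e)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-8)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-6)
        assert res.df == 2

    def test_label_permutation_invariance(self, rng):
        ga = (rng.exponential(5, 30) + 0.1, rng.random(30) < 0.8)
        gb = (rng.exponential(9, 25) + 0.1, rng.random(25) < 0.8)
        assert (logrank_test([ga, gb]).statistic
                == pytest.approx(logrank_test([gb, ga]).statistic, rel=1e-10))

    def test_gehan_identical_groups_null(self):
        g = (np.array([2.0, 4.0]), np.array([1, 1], bool))
        assert gehan_wilcoxon_test([g, g]).statistic == pytest.approx(0.0, abs=1e-12)

    def test_gehan_single_event_time_equals_logrank(self):
        # one common event time: the n-at-risk weight is a constant and
        # cancels from the standardized statistic
        ga = (np.array([5.0, 7.0]), np.array([1, 0], bool))
        gb = (np.array([5.0, 8.0]), np.array([0, 0], bool))
        assert (gehan_wilcoxon_test([ga, gb]).statistic
                == pytest.approx(logrank_test([ga, gb]).statistic, rel=1e-10))

    def test_gehan_matches_lifelines_wilcoxon(self, rng):
        ta = rng.exponential(5, 60) + 0.05
        tb = rng.exponential(10, 60) + 0.05
        ea = rng.random(60) < 0.8
        eb = rng.random(60) < 0.8
        res = gehan_wilcoxon_test([(ta, ea), (tb, eb)])
        ref = ll_logrank(ta, tb, ea, eb, weightings="wilcoxon")
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-8)

    def test_gehan_emphasizes_early_separation(self):
        """Hazards differing only early: Gehan weights upweight that window."""
        rng = np.random.default_rng(5)
        n = 150
        # group A: high early hazard that later matches B
        ta = np.where(rng.random(n) < 0.5, rng.exponential(1.0, n),
                      5 + rng.exponential(10.0, n)) + 0.01
        tb = 5 * rng.random(n) + rng.exponential(10.0, n) + 0.01
        ga = (ta, np.ones(n, bool))
        gb = (tb, np.ones(n, bool))
        assert (gehan_wilcoxon_test([ga, gb]).statistic
                > logrank_test([ga, gb]).statistic)

    def test_no_events_rejected(self):
        g1 = (np.array([1.0, 2.0]), np.zeros(2, bool))
        g2 = (np.array([3.0]), np.zeros(1, bool))
        with pytest.raises(ValueError):
            logrank_test([g1, g2])


class TestCox:
    def test_no_effect_coefficient_near_zero(self):
        t = np.tile(np.arange(1.0, 11.0), 2)
        e = np.ones(20, bool)
        x = np.repeat([0.0, 1.0], 10)
        m = cox_fit((t, e), x[:, None])
        assert abs(m.coefficients[0]) < 1e-6
        assert m.converged

    def test_four_subject_brute_force_partial_likelihood(self):
        """No ties: Newton solution equals the grid-maximized hand likelihood."""
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, bool)
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def neg_log_pl(b):
            ll = 0.0
            for i in range(4):
                risk = x[t >= t[i]]
                ll += b * x[i] - np.log(np.sum(np.exp(b * risk)))
            return -ll

        ref = minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded")
        m = cox_fit((t, e), x[:, None])
        assert m.coefficients[0] == pytest.approx(ref.x, abs=1e-5)
        assert m.log_partial_likelihood == pytest.approx(-ref.fun, abs=1e-8)

    def test_matches_lifelines_with_ties(self, rng):
        n = 150
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n).astype(float)
        t = np.ceil(rng.exponential(1.0 / np.exp(0.5 * x1 - 0.3 * x2)) * 8) / 2
        e = rng.random(n) < 0.8
        df = pd.DataFrame({"t": t, "e": e.astype(int), "x1": x1, "x2": x2})
        m = cox_fit((t, e), np.c_[x1, x2], ["x1", "x2"])
        cph = CoxPHFitter().fit(df, "t", "e")  # lifelines uses Efron ties
        assert np.allclose(m.coefficients, cph.params_.to_numpy(), atol=1e-5)
        assert np.allclose(m.standard_errors, cph.standard_errors_.to_numpy(),
                           atol=1e-4)

    def test_hr_recovery_true_2(self):
        rng = np.random.default_rng(42)
        t, e, x = _sim_two_groups(rng, 500, math.log(2.0), censor_scale=2.0)
        m = cox_fit((t, e), x[:, None].astype(float))
        assert abs(m.coefficients[0] - math.log(2.0)) < 3 * m.standard_errors[0]
        assert m.hazard_ratios[0] == pytest.approx(np.exp(m.coefficients[0]))

    def test_duplication_invariance(self, rng):
        """Replicating every record rescales the Breslow likelihood only.

        Duplication manufactures ties, so the exact invariance holds for
        the Breslow correction (risk-set ratios are scale-free); Efron's
        staggered adjustment perturbs the estimate slightly.
        """
        t, e, x = _sim_two_groups(rng, 60, 0.7, censor_scale=2.0)
        m1 = cox_fit((t, e), x[:, None].astype(float), ties_method="breslow")
        m2 = cox_fit((np.tile(t, 2), np.tile(e, 2)),
                     np.tile(x, 2)[:, None].astype(float),
                     ties_method="breslow")
        assert m2.coefficients[0] == pytest.approx(m1.coefficients[0], abs=1e-6)
        m2e = cox_fit((np.tile(t, 2), np.tile(e, 2)),
                      np.tile(x, 2)[:, None].astype(float))
        assert m2e.coefficients[0] == pytest.approx(m1.coefficients[0], abs=0.05)

    def test_efron_equals_breslow_without_ties(self, rng):
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.4 * x))  # continuous: no ties
        e = np.ones(n, bool)
        me = cox_fit((t, e), x[:, None], ties_method="efron")
        mb = cox_fit((t, e), x[:, None], ties_method="breslow")
        assert me.coefficients[0] == pytest.approx(mb.coefficients[0], abs=1e-10)
        assert me.log_partial_likelihood == pytest.approx(
            mb.log_partial_likelihood, abs=1e-8)

    def test_separation_flagged(self):
        # perfect separation: all x=1 die first
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.ones(6, bool)
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        m = cox_fit((t, e), x[:, None])
        assert m.separation_flag
        assert not m.converged

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            cox_fit((np.array([1.0, 2.0]), np.array([1, 1], bool)),
                    np.ones((2, 1)))


class TestScreenAndStepwise:
    def test_duplicated_covariate_identical_rows(self, rng):
        t, e, x = _sim_two_groups(rng, 100, 0.5, censor_scale=3.0)
        frame = pd.DataFrame({"a": x.astype(float), "b": x.astype(float)})
        out = univariate_screen((t, e), frame)
        a = out[out.covariate == "a"].iloc[0]
        b = out[out.covariate == "b"].iloc[0]
        assert a.coef == pytest.approx(b.coef)
        assert a.p == pytest.approx(b.p)

    def test_empty_covariate_set(self, rng):
        t, e, _ = _sim_two_groups(rng, 20, 0.0)
        out = univariate_screen((t, e), pd.DataFrame(index=range(20)))
        assert out.empty

    def test_screen_sorted_by_p(self, rng):
        n = 200
        x_strong = rng.integers(0, 2, n).astype(float)
        x_noise = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(1.0 * x_strong))
        e = np.ones(n, bool)
        out = univariate_screen((t, e), pd.DataFrame(
            {"noise": x_noise, "strong": x_strong}))
        assert out.iloc[0]["covariate"] == "strong"
        assert out["p"].is_monotonic_increasing

    def test_screen_null_type_i_error(self):
        """Wald p under the global null rejects at ~5%."""
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(25):
            n = 150
            t = rng.exponential(1.0, n)
            e = rng.random(n) < 0.8
            X = pd.DataFrame(rng.normal(size=(n, 20)),
                             columns=[f"c{j}" for j in range(20)])
            out = univariate_screen((t, e), X)
            pvals.extend(out["p"].tolist())
        frac = np.mean(np.asarray(pvals) < 0.05)
        # 500 null p-values; 3-sigma binomial band around 0.05
        assert 0.02 <= frac <= 0.08

    def test_strong_covariate_selected_first(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(10):
            n = 400
            X = pd.DataFrame(rng.normal(size=(n, 10)),
                             columns=[f"v{j}" for j in range(10)])
            t = rng.exponential(1.0 / np.exp(math.log(3.0) * X["v0"]))
            e = np.ones(n, bool)
            spec = StepwiseSpec(candidate_covariates=list(X.columns))
            _, trace = stepwise_cox((t, e), X, spec)
            entered = [s["covariate"] for s in trace if s["action"] == "enter"]
            hits += bool(entered and entered[0] == "v0")
        assert hits >= 9

    def test_p_enter_one_admits_everything(self, rng):
        n = 120
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        t = rng.exponential(1.0, n)
        e = np.ones(n, bool)
        spec = StepwiseSpec(candidate_covariates=list("abcd"), p_enter=1.0)
        model, _ = stepwise_cox((t, e), X, spec)
        assert sorted(model.covariate_names) == list("abcd")

    def test_forced_in_only(self, rng):
        n = 100
        X = pd.DataFrame({"age": rng.normal(60, 10, n)})
        t = rng.exponential(1.0, n)
        e = np.ones(n, bool)
        spec = StepwiseSpec(candidate_covariates=[], forced_in_covariates=["age"])
        model, trace = stepwise_cox((t, e), X, spec)
        assert model.covariate_names == ["age"]
        assert trace[0]["action"] == "force_in"
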