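"""Kaplan–Meier, log-rank, Cox (Breslow) and mean-survival summaries."""

import numpy as np
import pytest

from conftest import logrank_oracle
from pdoscore.survival import (
    cox_binary,
    km_estimate,
    logrank_statistic,
    mean_survival,
    _breslow_terms,
)


class TestKaplanMeier:
    def test_worked_five_subject_curve(self, toy_survival):
        """3, 5+, 7, 9, 11+: hand-computed product-limit steps."""
        t, e = toy_survival
        curve = km_estimate(t, e)
        assert curve.survival_at(3) == pytest.approx(4 / 5)
        assert curve.survival_at(7) == pytest.approx(4 / 5 * 2 / 3)
        assert curve.survival_at(9) == pytest.approx(4 / 5 * 2 / 3 * 1 / 2)
        assert curve.survival_at(1) == 1.0

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=40)
        curve = km_estimate(t, np.ones(40, bool))
        for q in (np.min(t), np.median(t), np.max(t)):
            assert curve.survival_at(q) == pytest.approx(np.mean(t > q), abs=1e-12)

    def test_all_censored_curve_stays_flat_at_one(self):
        curve = km_estimate([5, 10, 15], [False, False, False])
        assert np.all(curve.survival == 1.0)

    def test_merged_identical_groups_reproduce_group_curve(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        e = np.array([True, False, True, True])
        single = km_estimate(t, e)
        merged = km_estimate(np.tile(t, 2), np.tile(e, 2))
        assert np.allclose(single.survival, merged.survival)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, True, False, True]
        res = logrank_statistic(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(3)
        ta, tb = rng.exponential(5, 12), rng.exponential(9, 15)
        ea, eb = np.ones(12, bool), np.ones(15, bool)
        fwd = logrank_statistic(ta, ea, tb, eb)
        rev = logrank_statistic(tb, eb, ta, ea)
        assert fwd.statistic == pytest.approx(rev.statistic, rel=1e-10)

    def test_six_subject_toy_matches_risk_set_oracle(self):
        """Events at 1,2,3 in A and 4,5,6 in B: hand hypergeometric sum 5.0517."""
        ta, tb = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        ea = eb = [True, True, True]
        res = logrank_statistic(ta, ea, tb, eb)
        oracle = logrank_oracle(ta, ea, tb, eb)
        assert oracle == pytest.approx(3.4225 / 0.6775, rel=1e-12)
        assert res.statistic == pytest.approx(oracle, rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_oracle_on_random_small_cohorts(self, seed):
        """Risk-set-table oracle equivalence on n <= 25 with ties and censoring."""
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(4, 13), rng.integers(4, 13)
        ta = rng.integers(1, 10, na).astype(float)  # integer times force ties
        tb = rng.integers(1, 10, nb).astype(float)
        ea = rng.uniform(size=na) < 0.8
        eb = rng.uniform(size=nb) < 0.8
        if not (ea.any() or eb.any()):
            ea[0] = True
        res = logrank_statistic(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(logrank_oracle(ta, ea, tb, eb), rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_statistic([], [], [1.0], [True])


class TestCoxBinary:
    def test_identical_distributions_hr_near_one(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10, 400)
        e = np.ones(400, bool)
        g = np.arange(400) % 2
        res = cox_binary(t, e, g)
        assert res.hazard_ratio == pytest.approx(1.0, abs=0.35)
        assert res.ci_lower < 1.0 < res.ci_upper

    def test_label_swap_inverts_hazard_ratio(self):
        rng = np.random.default_rng(11)
        t = np.concatenate([rng.exponential(4, 30), rng.exponential(12, 30)])
        e = np.ones(60, bool)
        g = np.repeat([0, 1], 30)
        res = cox_binary(t, e, g)
        res_swapped = cox_binary(t, e, 1 - g)
        assert res_swapped.hazard_ratio == pytest.approx(1 / res.hazard_ratio, rel=1e-6)

    def test_parameter_recovery_true_hr_02(self):
        """Exponential arms, true HR 0.2, n=200/arm: mean bias within 0.05 over 100 seeds."""
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t0 = rng.exponential(1 / 0.1, 200)
            t1 = rng.exponential(1 / 0.02, 200)
            t = np.concatenate([t0, t1])
            e = t < 60.0
            t = np.minimum(t, 60.0)
            g = np.repeat([0, 1], 200)
            estimates.append(cox_binary(t, e, g).hazard_ratio)
        assert abs(np.mean(estimates) - 0.2) < 0.05

    def test_matches_lifelines_on_tie_free_data(self):
        """Breslow and Efron coincide without ties; cross-check vs lifelines."""
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        t = np.concatenate([rng.exponential(5, 40), rng.exponential(10, 40)])
        e = rng.uniform(size=80) < 0.9
        g = np.repeat([0, 1], 40)
        mine = cox_binary(t, e, g)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e.astype(int), "g": g}), "t", "e"
        )
        assert mine.coef == pytest.approx(float(cph.params_["g"]), abs=1e-6)
        assert mine.se == pytest.approx(float(cph.standard_errors_["g"]), abs=1e-6)

    def test_score_test_at_zero_equals_logrank(self):
        """Classical identity: the Cox score statistic at beta=0 is the
        log-rank chi-square (tie-free data)."""
        rng = np.random.default_rng(13)
        t = rng.exponential(8, 50) + rng.uniform(0, 1e-6, 50)  # continuous: no ties
        e = rng.uniform(size=50) < 0.8
        g = (rng.uniform(size=50) < 0.5).astype(int)
        e[np.where(g == 0)[0][0]] = True
        e[np.where(g == 1)[0][0]] = True
        terms = _breslow_terms(t, e, g)
        s1 = sum(term[3] for term in terms)
        u = s1 - sum(d * n1 / (n0 + n1) for n0, n1, d, _ in terms)
        info = sum(
            d * (n1 / (n0 + n1)) * (1 - n1 / (n0 + n1)) for n0, n1, d, _ in terms
        )
        lr = logrank_statistic(t[g == 0], e[g == 0], t[g == 1], e[g == 1])
        assert u**2 / info == pytest.approx(lr.statistic, rel=1e-6)

    def test_zero_event_group_flagged_and_capped(self):
        t = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        e = [True, True, True, False, False, False]
        g = [0, 0, 0, 1, 1, 1]
        res = cox_binary(t, e, g)
        assert not res.estimable
        assert abs(res.coef) <= 15.0

    def test_small_event_counts_flagged_unstable(self):
        t = [1.0, 2.0, 30.0, 40.0]
        e = [True, False, True, False]
        g = [0, 0, 1, 1]
        assert cox_binary(t, e, g).unstable


class TestMeanSurvival:
    def test_single_subject_both_methods_agree(self):
        for method in ("arithmetic", "rmst"):
            s = mean_survival([10.0, 20.0], [True, True], [0, 1], method=method, horizon=60)
            assert s.mean_by_group[0] == pytest.approx(10.0)
            assert s.mean_by_group[1] == pytest.approx(20.0)
            assert s.difference == pytest.approx(10.0)

    def test_no_censoring_arithmetic_equals_rmst_beyond_max_time(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 30)
        e = np.ones(30, bool)
        g = np.zeros(30, int)
        arith = mean_survival(t, e, g, method="arithmetic")
        rmst = mean_survival(t, e, g, method="rmst", horizon=float(t.max() + 1))
        assert arith.mean_by_group[0] == pytest.approx(rmst.mean_by_group[0], rel=1e-9)
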