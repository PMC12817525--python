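"""Exact agreement statistics against brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from conftest import binom_pmf_oracle
from pdoscore.concordance import (
    ConfusionTable,
    clopper_pearson_ci,
    cohens_kappa,
    concordance_report,
    confusion_from_labels,
    directional_concordance,
    exact_binomial_p,
    exact_mcnemar,
    kappa_from_contingency,
    paired_correctness_mcnemar,
    rank_correlations,
)
from pdoscore.outcomes import Direction


PRE = ConfusionTable(tp=4, fp=2, fn=1, tn=11)
POST = ConfusionTable(tp=7, fp=0, fn=2, tn=4)


class TestConfusionTable:
    def test_counts_from_labels(self):
        pred = [True] * 6 + [False] * 12
        truth = [True] * 4 + [False] * 2 + [True] + [False] * 11
        t = confusion_from_labels(pred, truth)
        assert (t.tp, t.fp, t.fn, t.tn) == (4, 2, 1, 11)

    def test_all_agree_has_no_discordant_cells(self):
        t = confusion_from_labels([True, False, True], [True, False, True])
        assert t.fp == t.fn == 0

    def test_length_mismatch_and_missing_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_labels([True], [True, False])
        with pytest.raises(ValueError, match="missing"):
            confusion_from_labels(np.array([True, None], dtype=object), np.array([True, False], dtype=object))

    def test_derived_metrics_consistent(self):
        assert PRE.accuracy == pytest.approx(15 / 18)
        assert PRE.balanced_accuracy == pytest.approx((PRE.sensitivity + PRE.specificity) / 2)
        assert PRE.discordant == (1, 2)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k, n, lo, hi",
        [
            (15, 18, 58.6, 96.4),
            (11, 13, 54.6, 98.1),
            (4, 5, 28.4, 99.5),
            (4, 6, 22.3, 95.7),
            (11, 12, 61.5, 99.8),
            (7, 9, 40.0, 97.2),
            (4, 4, 39.8, 100.0),
            (9, 13, 38.6, 90.9),
        ],
    )
    def test_matches_printed_intervals_to_one_decimal(self, k, n, lo, hi):
        lower, upper = clopper_pearson_ci(k, n)
        assert round(100 * lower, 1) == lo
        assert round(100 * upper, 1) == hi

    def test_degenerate_endpoints(self):
        assert clopper_pearson_ci(0, 10)[0] == 0.0
        assert clopper_pearson_ci(10, 10)[1] == 1.0

    def test_coverage_at_least_nominal(self):
        """10^4 binomial draws per (p, n): empirical coverage >= 95%."""
        rng = np.random.default_rng(0)
        for p in (0.2, 0.5, 0.8):
            for n in (10, 20):
                ks = rng.binomial(n, p, size=10_000)
                alpha = 0.05
                lowers = np.where(ks == 0, 0.0, sps.beta.ppf(alpha / 2, ks, n - ks + 1))
                uppers = np.where(ks == n, 1.0, sps.beta.ppf(1 - alpha / 2, ks + 1, np.maximum(n - ks, 1)))
                coverage = np.mean((lowers <= p) & (p <= uppers))
                assert coverage >= 0.95

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(5, 4)


class TestExactBinomial:
    @pytest.mark.parametrize("k, n, printed", [(15, 18, 0.0038), (11, 13, 0.0112)])
    def test_upper_tail_matches_pmf_oracle(self, k, n, printed):
        oracle = sum(binom_pmf_oracle(i, n) for i in range(k, n + 1))
        p = exact_binomial_p(k, n)
        assert p == pytest.approx(oracle, rel=1e-12)
        assert round(p, 4) == printed

    @pytest.mark.parametrize("n", [3, 8, 15])
    def test_all_successes_closed_form(self, n):
        assert exact_binomial_p(n, n) == pytest.approx(0.5**n, rel=1e-12)

    @pytest.mark.parametrize("k,n", [(0, 5), (3, 7), (12, 25), (20, 25)])
    def test_agrees_with_enumeration_up_to_n25(self, k, n):
        oracle = sum(binom_pmf_oracle(i, n) for i in range(k, n + 1))
        assert exact_binomial_p(k, n) == pytest.approx(oracle, rel=1e-12)


class TestKappa:
    @pytest.mark.parametrize(
        "table, expected",
        [(PRE, 0.609), (POST, 0.68), (ConfusionTable(5, 0, 4, 4), 0.43)],
    )
    def test_reference_tables(self, table, expected):
        assert round(cohens_kappa(table), 2) == pytest.approx(round(expected, 2))

    def test_perfect_diagonal_is_one(self):
        assert cohens_kappa(ConfusionTable(tp=6, fp=0, fn=0, tn=9)) == 1.0

    def test_polarity_swap_invariance(self):
        """Swapping both methods' positive class leaves kappa unchanged."""
        t = ConfusionTable(tp=4, fp=2, fn=1, tn=11)
        swapped = ConfusionTable(tp=t.tn, fp=t.fn, fn=t.fp, tn=t.tp)
        assert cohens_kappa(t) == pytest.approx(cohens_kappa(swapped))

    def test_zero_when_rows_proportional_to_marginals(self):
        # rows both 3:1 -> observed agreement equals chance agreement
        assert cohens_kappa(ConfusionTable(tp=9, fp=3, fn=3, tn=1)) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_expected_agreement(self):
        """Both raters constant on the same category: Pe = Po = 1, kappa = 1."""
        assert kappa_from_contingency(np.array([[5, 0], [0, 0]])) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_sklearn_on_random_labels(self, seed):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, 30).astype(bool)
        b = rng.integers(0, 2, 30).astype(bool)
        t = confusion_from_labels(a, b)
        assert cohens_kappa(t) == pytest.approx(cohen_kappa_score(a, b), rel=1e-9)


class TestExactMcNemar:
    @pytest.mark.parametrize(
        "b, c, expected",
        [(1, 2, 1.000), (2, 0, 0.50), (0, 0, 1.0), (3, 1, 0.625), (0, 6, 0.03125)],
    )
    def test_reference_values(self, b, c, expected):
        assert exact_mcnemar(b, c) == pytest.approx(expected, abs=1e-9)

    @given(st.integers(0, 25), st.integers(0, 25))
    @settings(derandomize=True)
    def test_symmetric_and_bounded(self, b, c):
        p = exact_mcnemar(b, c)
        assert p == pytest.approx(exact_mcnemar(c, b))
        assert 0 < p <= 1.0

    @given(st.integers(0, 25), st.integers(0, 25))
    @settings(derandomize=True, max_examples=40)
    def test_matches_pmf_enumeration_oracle(self, b, c):
        n = b + c
        if n == 0:
            assert exact_mcnemar(b, c) == 1.0
            return
        lower = sum(binom_pmf_oracle(i, n) for i in range(0, b + 1))
        upper = sum(binom_pmf_oracle(i, n) for i in range(b, n + 1))
        oracle = min(1.0, 2 * min(lower, upper))
        assert exact_mcnemar(b, c) == pytest.approx(oracle, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_mcnemar(-1, 2)


class TestPairedCorrectness:
    def test_reference_head_to_head(self):
        """3 score-only vs 1 imaging-only correct: exact McNemar P = 0.625."""
        correct1 = [True] * 9 + [False] * 1 + [True] * 3
        correct2 = [True] * 9 + [True] * 1 + [False] * 3
        res = paired_correctness_mcnemar(correct1, correct2)
        assert res.only_method1_correct == 3
        assert res.only_method2_correct == 1
        assert res.exact_mcnemar_p == pytest.approx(0.625)
        assert res.n == 13

    def test_identical_vectors_give_p_one(self):
        v = [True, False, True, True]
        assert paired_correctness_mcnemar(v, v).exact_mcnemar_p == 1.0


class TestRankCorrelations:
    def test_perfect_monotone(self):
        res = rank_correlations([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.kendall_tau_b == pytest.approx(1.0)

    def test_reversal_flips_sign(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [3, 1, 4, 1, 5, 9]
        fwd = rank_correlations(x, y)
        rev = rank_correlations(x[::-1], y)
        assert rev.spearman_rho == pytest.approx(-fwd.spearman_rho)
        assert rev.kendall_tau_b == pytest.approx(-fwd.kendall_tau_b)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rank_correlations([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_p_matches_per_permutation_oracle_with_ties(self):
        """7-pair toy with ties: full enumeration via per-permutation scipy
        calls reproduces both exact p-values."""
        x = np.array([-2.0, 0.0, 1.0, 1.0, 3.0, -1.0, 2.0])
        y = np.array([-1.0, 0.0, 0.0, 2.0, 4.0, -3.0, 1.0])
        res = rank_correlations(x, y)
        assert res.exact

        rho_obs = sps.spearmanr(x, y).statistic
        tau_obs = sps.kendalltau(x, y).statistic
        ge_rho = ge_tau = 0
        total = 0
        for perm in itertools.permutations(y):
            total += 1
            ge_rho += abs(sps.spearmanr(x, perm).statistic) >= abs(rho_obs) - 1e-12
            ge_tau += abs(sps.kendalltau(x, perm).statistic) >= abs(tau_obs) - 1e-12
        assert res.spearman_p == pytest.approx(ge_rho / total, rel=1e-12)
        assert res.kendall_p == pytest.approx(ge_tau / total, rel=1e-12)
        assert res.spearman_rho == pytest.approx(rho_obs)
        assert res.kendall_tau_b == pytest.approx(tau_obs)

    def test_large_n_falls_back_to_asymptotic(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = rank_correlations(x, y)
        assert not res.exact
        assert res.spearman_p == pytest.approx(sps.spearmanr(x, y).pvalue)


class TestDirectionalConcordance:
    def test_reference_agreement_fraction(self):
        d1 = [Direction.IMPROVED] * 2 + [Direction.STABLE] * 3 + [Direction.WORSENED] * 3
        d2 = [Direction.IMPROVED] * 2 + [Direction.STABLE] * 3 + [Direction.WORSENED] * 1 + [Direction.STABLE] * 2
        res = directional_concordance(d1, d2)
        assert res.agreement == pytest.approx(6 / 8)

    def test_full_agreement(self):
        d = [Direction.IMPROVED, Direction.STABLE, Direction.WORSENED]
        res = directional_concordance(d, d)
        assert res.agreement == 1.0
        assert res.kappa == 1.0

    def test_kappa_matches_hand_arithmetic(self):
        d1 = [Direction.IMPROVED] * 3 + [Direction.STABLE] * 3 + [Direction.WORSENED] * 2
        d2 = [Direction.IMPROVED] * 2 + [Direction.STABLE] * 4 + [Direction.WORSENED] * 2
        res = directional_concordance(d1, d2)
        table = res.table
        n = table.sum()
        po = np.trace(table) / n
        pe = sum(table[i].sum() * table[:, i].sum() for i in range(3)) / n**2
        assert res.kappa == pytest.approx((po - pe) / (1 - pe))


class TestReportBattery:
    def test_reference_pre_treatment_battery(self):
        rep = concordance_report(PRE)
        assert round(100 * rep.accuracy, 1) == 83.3
        assert round(100 * rep.sensitivity, 1) == 80.0
        assert round(100 * rep.specificity, 1) == 84.6
        assert round(100 * rep.ppv, 1) == 66.7
        assert round(100 * rep.npv, 1) == 91.7
        assert rep.mcnemar_p == pytest.approx(1.000)
        assert rep.accuracy_ci[0] <= rep.accuracy <= rep.accuracy_ci[1]

    def test_balanced_accuracy_identity(self):
        rep = concordance_report(POST)
        assert rep.balanced_accuracy == pytest.approx((rep.sensitivity + rep.specificity) / 2)
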