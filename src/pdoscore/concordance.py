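"""Prediction-versus-ground-truth agreement statistics.

Everything the small-cohort validation of an ex vivo predictor needs:
confusion-table metrics with exact (Clopper–Pearson) confidence intervals,
exact binomial tests against chance, Cohen's kappa, the exact McNemar test
on discordant pairs (both the marginal form and the paired-correctness form
comparing two predictors), balanced accuracy, three-level directional
concordance, and tie-aware rank correlations with exact permutation
p-values at small n.

Throughout, the positive class is the *adverse* outcome (nonresponse / PD /
recurrence), so sensitivity is the detection rate for treatment failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import islice, permutations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .outcomes import Direction

__all__ = [
    "ConfusionTable",
    "ConcordanceReport",
    "PairedCorrectnessComparison",
    "RankCorrelationResult",
    "DirectionalConcordance",
    "confusion_from_labels",
    "clopper_pearson_ci",
    "exact_binomial_p",
    "cohens_kappa",
    "kappa_from_contingency",
    "exact_mcnemar",
    "paired_correctness_mcnemar",
    "rank_correlations",
    "directional_concordance",
    "concordance_report",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts; positive class = adverse outcome (nonresponse / PD)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")
        if self.n < 1:
            raise ValueError("confusion table must hold at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        """NaN when the truth holds no positives."""
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        """NaN when the truth holds no negatives."""
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2

    @property
    def discordant(self) -> tuple[int, int]:
        """(b, c) = (false negatives, false positives) — the off-diagonal
        cells entering the marginal McNemar test."""
        return (self.fn, self.fp)


def confusion_from_labels(
    predicted: Sequence[bool], truth: Sequence[bool]
) -> ConfusionTable:
    """Cross-tabulate binary predictions against truth.

    Inputs are boolean sequences where ``True`` marks the positive
    (adverse) class.  Lengths must match and entries must not be missing.
    """
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("predicted and truth must be equal-length 1-D sequences")
    if p.size == 0:
        raise ValueError("empty label sequences")
    for arr, name in ((p, "predicted"), (t, "truth")):
        if arr.dtype == object and any(v is None for v in arr):
            raise ValueError(f"{name} contains missing labels")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionTable(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper–Pearson) confidence interval from beta quantiles."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    alpha = 1 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (lower, upper)


def exact_binomial_p(
    k: int, n: int, p0: float = 0.5, alternative: str = "greater"
) -> float:
    """Exact binomial test of k successes in n trials against p0.

    Default is the one-sided upper tail P(X >= k), the form under which the
    small-cohort accuracy tests here reproduce to the printed precision.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(stats.binomtest(k, n, p0, alternative=alternative).pvalue)


def cohens_kappa(table: ConfusionTable) -> float:
    """Chance-corrected 2x2 agreement, (Po - Pe)/(1 - Pe).

    Pe uses the marginal-product expected agreement.  The degenerate case
    Pe = 1 yields kappa = 1 when observed agreement is also perfect and
    raises otherwise.
    """
    return kappa_from_contingency(
        np.array([[table.tp, table.fn], [table.fp, table.tn]], dtype=float)
    )


def kappa_from_contingency(table: np.ndarray) -> float:
    """Unweighted Cohen's kappa for a square contingency table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("contingency table must be square")
    n = table.sum()
    if n < 1:
        raise ValueError("empty contingency table")
    po = np.trace(table) / n
    pe = float(np.sum(table.sum(axis=0) * table.sum(axis=1)) / n**2)
    if pe >= 1.0 - 1e-15:
        if po >= 1.0 - 1e-15:
            return 1.0
        raise ZeroDivisionError("expected agreement is 1: kappa undefined")
    return float((po - pe) / (1 - pe))


def exact_mcnemar(b: int, c: int) -> float:
    """Two-sided exact McNemar test on the discordant-pair counts.

    Binomial test of b successes in b + c trials at 0.5:
    p = min(1, 2 * min(P(X <= b), P(X >= b))); with no discordant pairs the
    test is vacuous and p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be >= 0")
    n = b + c
    if n == 0:
        return 1.0
    lower = float(stats.binom.cdf(b, n, 0.5))
    upper = float(stats.binom.sf(b - 1, n, 0.5))
    return min(1.0, 2.0 * min(lower, upper))


@dataclass(frozen=True)
class PairedCorrectnessComparison:
    """Head-to-head correctness of two predictors on the same subjects."""

    both_correct: int
    only_method1_correct: int
    only_method2_correct: int
    both_wrong: int
    exact_mcnemar_p: float

    @property
    def n(self) -> int:
        return (
            self.both_correct
            + self.only_method1_correct
            + self.only_method2_correct
            + self.both_wrong
        )


def paired_correctness_mcnemar(
    correct1: Sequence[bool], correct2: Sequence[bool]
) -> PairedCorrectnessComparison:
    """Exact McNemar comparison of two predictors' per-subject correctness."""
    c1 = np.asarray(correct1, dtype=bool)
    c2 = np.asarray(correct2, dtype=bool)
    if c1.shape != c2.shape or c1.ndim != 1:
        raise ValueError("correctness vectors must be equal-length 1-D sequences")
    only1 = int(np.sum(c1 & ~c2))
    only2 = int(np.sum(~c1 & c2))
    return PairedCorrectnessComparison(
        both_correct=int(np.sum(c1 & c2)),
        only_method1_correct=only1,
        only_method2_correct=only2,
        both_wrong=int(np.sum(~c1 & ~c2)),
        exact_mcnemar_p=exact_mcnemar(only1, only2),
    )


@dataclass(frozen=True)
class RankCorrelationResult:
    spearman_rho: float
    spearman_p: float
    kendall_tau_b: float
    kendall_p: float
    exact: bool        # True when p-values come from full permutation enumeration


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    ii, jj = np.triu_indices(n, k=1)
    return ii, jj


def _perm_pvalues(rx: np.ndarray, y: np.ndarray, rho_obs: float, tau_obs: float) -> tuple[float, float]:
    """Exact two-sided permutation p-values by full enumeration over y-orderings.

    Spearman's rho is the Pearson correlation of the (tie-averaged) ranks;
    Kendall's tau-b shares its tie-corrected denominator across
    permutations, so only the concordant-minus-discordant sum varies.
    Enumeration is chunked to bound memory at large n (n <= 10 supported).
    """
    n = y.size
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom_rho = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))

    ii, jj = _pair_indices(n)
    sx = np.sign(rx[ii] - rx[jj]).astype(np.int8)
    sign_y = np.sign(y[:, None] - y[None, :]).astype(np.int8)
    tx = np.sum(sx == 0)
    sy_full = np.sign(y[ii] - y[jj])
    ty = np.sum(sy_full == 0)
    n0 = n * (n - 1) // 2
    denom_tau = math.sqrt((n0 - tx) * (n0 - ty))

    total = math.factorial(n)
    ge_rho = 0
    ge_tau = 0
    perm_iter = permutations(range(n))
    chunk_size = 40320
    while True:
        chunk = np.array(list(islice(perm_iter, chunk_size)), dtype=np.intp)
        if chunk.size == 0:
            break
        rho = (ry_c[chunk] @ rx_c) / denom_rho
        sy = sign_y[chunk[:, ii], chunk[:, jj]]
        tau = (sy @ sx.astype(np.int64)) / denom_tau
        ge_rho += int(np.sum(np.abs(rho) >= abs(rho_obs) - 1e-12))
        ge_tau += int(np.sum(np.abs(tau) >= abs(tau_obs) - 1e-12))
    return ge_rho / total, ge_tau / total


def rank_correlations(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 10
) -> RankCorrelationResult:
    """Spearman rho (average ranks for ties) and Kendall tau-b.

    For n <= ``exact_max_n`` the two-sided p-values are exact, from full
    enumeration of all n! pairings; beyond that the scipy asymptotic
    p-values are used.  Requires n >= 3 and non-constant inputs.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("correlation undefined for a constant vector")

    rho_res = stats.spearmanr(xa, ya)
    tau_res = stats.kendalltau(xa, ya)  # tau-b with tie correction
    rho, tau = float(rho_res.statistic), float(tau_res.statistic)
    if n <= exact_max_n:
        rx = stats.rankdata(xa)
        rho_p, tau_p = _perm_pvalues(rx, ya, rho, tau)
        return RankCorrelationResult(rho, rho_p, tau, tau_p, exact=True)
    return RankCorrelationResult(
        rho, float(rho_res.pvalue), tau, float(tau_res.pvalue), exact=False
    )


@dataclass(frozen=True)
class DirectionalConcordance:
    agreement: float
    kappa: float
    table: np.ndarray  # 3x3 contingency, rows = method 1, cols = method 2
    n: int


_DIRECTIONS = (Direction.IMPROVED, Direction.STABLE, Direction.WORSENED)


def directional_concordance(
    dir1: Sequence[Direction], dir2: Sequence[Direction]
) -> DirectionalConcordance:
    """Three-level (improved/stable/worsened) agreement with unweighted kappa."""
    d1 = [Direction(d) for d in dir1]
    d2 = [Direction(d) for d in dir2]
    if len(d1) != len(d2):
        raise ValueError("direction sequences must have equal length")
    if len(d1) == 0:
        raise ValueError("empty direction sequences")
    idx = {d: i for i, d in enumerate(_DIRECTIONS)}
    table = np.zeros((3, 3), dtype=float)
    for a, b in zip(d1, d2):
        table[idx[a], idx[b]] += 1
    n = len(d1)
    agreement = float(np.trace(table) / n)
    return DirectionalConcordance(
        agreement=agreement, kappa=kappa_from_contingency(table), table=table, n=n
    )


@dataclass(frozen=True)
class ConcordanceReport:
    """The full confusion-metric battery with exact intervals and tests."""

    table: ConfusionTable
    accuracy: float
    accuracy_ci: tuple[float, float]
    accuracy_exact_binomial_p: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    balanced_accuracy: float
    kappa: float
    mcnemar_p: float

    def to_dict(self) -> dict:
        return {
            "n": self.table.n,
            "accuracy": self.accuracy,
            "accuracy_ci_lower": self.accuracy_ci[0],
            "accuracy_ci_upper": self.accuracy_ci[1],
            "accuracy_exact_binomial_p": self.accuracy_exact_binomial_p,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "balanced_accuracy": self.balanced_accuracy,
            "kappa": self.kappa,
            "mcnemar_p": self.mcnemar_p,
        }


def concordance_report(
    table: ConfusionTable,
    level: float = 0.95,
    p0: float = 0.5,
    alternative: str = "greater",
) -> ConcordanceReport:
    """Compute the full agreement battery from a 2x2 table.

    The exact binomial p tests overall accuracy against chance (p0 = 0.5),
    one-sided by default; Clopper–Pearson intervals accompany every
    proportion.
    """
    t = table

    def _ci(k: int, n: int) -> tuple[float, float]:
        # an empty margin has no interval
        return clopper_pearson_ci(k, n, level) if n else (float("nan"), float("nan"))

    return ConcordanceReport(
        table=t,
        accuracy=t.accuracy,
        accuracy_ci=_ci(t.tp + t.tn, t.n),
        accuracy_exact_binomial_p=exact_binomial_p(t.tp + t.tn, t.n, p0, alternative),
        sensitivity=t.sensitivity,
        sensitivity_ci=_ci(t.tp, t.tp + t.fn),
        specificity=t.specificity,
        specificity_ci=_ci(t.tn, t.tn + t.fp),
        ppv=t.ppv,
        ppv_ci=_ci(t.tp, t.tp + t.fp),
        npv=t.npv,
        npv_ci=_ci(t.tn, t.tn + t.fn),
        balanced_accuracy=t.balanced_accuracy,
        kappa=cohens_kappa(t),
        mcnemar_p=exact_mcnemar(*t.discordant),
    )
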