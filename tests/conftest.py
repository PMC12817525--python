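import numpy as np
import pytest

from pdoscore.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default-shape cohort (23 patients / 31 samples), seed 1."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture()
def toy_survival():
    """Five-subject worked KM set: 3, 5+, 7, 9, 11+ (+ = censored)."""
    return np.array([3.0, 5.0, 7.0, 9.0, 11.0]), np.array([True, False, True, True, False])


def logrank_oracle(times_a, events_a, times_b, events_b):
    """First-principles log-rank chi-square: hypergeometric sums over risk sets.

    Independent of the package implementation — iterates distinct event
    times, tabulating observed minus expected events in group A with the
    hypergeometric variance.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    o_minus_e = 0.0
    var = 0.0
    for tau in np.unique(t[e]):
        at_risk = t >= tau
        n = at_risk.sum()
        n_a = (at_risk & (grp == 0)).sum()
        d = (e & (t == tau)).sum()
        d_a = (e & (t == tau) & (grp == 0)).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n - d) / (n - 1) * (n_a / n) * (1 - n_a / n)
    return o_minus_e**2 / var


def binom_pmf_oracle(k, n):
    """Binomial(n, 1/2) point mass by direct combinatorics."""
    from math import comb

    return comb(n, k) / 2**n
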