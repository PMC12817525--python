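"""Survival-optimal dichotomization of an ordinal score.

Maximally selected rank statistics over a *restricted* candidate set: each
candidate midpoint c splits the cohort into score <= c versus score > c,
the two groups are compared by the log-rank test, and the admissible
candidate with the largest statistic wins.  Restricting candidates to
ordinal midpoints (default 3.5 / 4.5 / 5.5 for a 0–12 tier-sum score) and
enforcing a minimum group proportion (default 0.25) keeps the selected
threshold interpretable and prevents degenerate splits.  Stability is
assessed by resampling subjects with replacement and recording how often
each candidate is selected.

Per-candidate p-values are plain log-rank p-values, unadjusted for the
maximal selection; they describe each split in isolation, not the selection
procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .survival import logrank_statistic

__all__ = [
    "CutpointConfig",
    "CandidateStat",
    "CutpointResult",
    "NoAdmissibleCutpointError",
    "maxstat_select",
    "bootstrap_stability",
]


class NoAdmissibleCutpointError(ValueError):
    """No candidate satisfies the minimum-group-proportion constraint."""


@dataclass(frozen=True)
class CutpointConfig:
    candidates: tuple[float, ...] = (3.5, 4.5, 5.5)
    minprop: float = 0.25
    bootstrap_reps: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.minprop <= 0.5:
            raise ValueError("minprop must lie in (0, 0.5]")
        cands = tuple(float(c) for c in self.candidates)
        if len(cands) == 0 or any(b <= a for a, b in zip(cands, cands[1:])):
            raise ValueError("candidates must be non-empty and strictly increasing")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        object.__setattr__(self, "candidates", cands)


@dataclass(frozen=True)
class CandidateStat:
    cutoff: float
    n_low: int
    n_high: int
    valid: bool                      # minprop satisfied on both sides
    statistic: Optional[float]       # log-rank chi-square (None if invalid)
    p_value: Optional[float]         # unadjusted for selection


@dataclass(frozen=True)
class CutpointResult:
    best_cutoff: float
    candidates: tuple[CandidateStat, ...]
    endpoint: str = "DFS"
    selection_frequency: Optional[dict] = None  # filled by bootstrap_stability


def _validate(scores, durations, events):
    s = np.asarray(scores, dtype=float)
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (s.shape == t.shape == e.shape) or s.ndim != 1:
        raise ValueError("scores, durations and events must be aligned 1-D arrays")
    if s.size < 2:
        raise ValueError("need at least 2 subjects")
    return s, t, e


def maxstat_select(
    scores: Sequence[float],
    durations: Sequence[float],
    events: Sequence[bool],
    config: CutpointConfig = CutpointConfig(),
    endpoint: str = "DFS",
) -> CutpointResult:
    """Pick the admissible candidate cutoff with the maximal log-rank statistic.

    A candidate is admissible when both sides of the split retain at least
    ``ceil(minprop * n)`` subjects.  Ties in the statistic break toward the
    lowest cutoff (deterministic, and it favours a larger "sensitive"
    group).  Raises :class:`NoAdmissibleCutpointError` when no candidate is
    admissible (e.g. constant scores).
    """
    s, t, e = _validate(scores, durations, events)
    n = s.size
    min_group = math.ceil(config.minprop * n)

    stats_out: list[CandidateStat] = []
    best: Optional[tuple[float, float]] = None  # (statistic, cutoff)
    for c in config.candidates:
        low = s <= c
        n_low, n_high = int(low.sum()), int((~low).sum())
        valid = n_low >= min_group and n_high >= min_group
        if not valid:
            stats_out.append(CandidateStat(c, n_low, n_high, False, None, None))
            continue
        lr = logrank_statistic(t[low], e[low], t[~low], e[~low])
        stats_out.append(CandidateStat(c, n_low, n_high, True, lr.statistic, lr.p_value))
        # strict > keeps the lowest cutoff on ties
        if best is None or lr.statistic > best[0] + 1e-12:
            best = (lr.statistic, c)

    if best is None:
        raise NoAdmissibleCutpointError(
            f"no candidate cutoff keeps both groups >= {min_group} subjects "
            f"(n={n}, minprop={config.minprop})"
        )
    return CutpointResult(best_cutoff=best[1], candidates=tuple(stats_out), endpoint=endpoint)


def bootstrap_stability(
    scores: Sequence[float],
    durations: Sequence[float],
    events: Sequence[bool],
    config: CutpointConfig = CutpointConfig(),
    endpoint: str = "DFS",
) -> CutpointResult:
    """Bootstrap selection frequencies for each candidate cutoff.

    Subjects are resampled with replacement ``bootstrap_reps`` times
    (seeded by ``config.seed``); :func:`maxstat_select` runs on each
    resample.  Resamples where no candidate is admissible are counted under
    the ``"none"`` key, so the frequencies sum to 1 including that bucket.
    The full-sample selection result is returned with the frequency map
    attached.
    """
    s, t, e = _validate(scores, durations, events)
    full = maxstat_select(s, t, e, config, endpoint)
    rng = np.random.default_rng(config.seed)
    counts: dict = {c: 0 for c in config.candidates}
    counts["none"] = 0
    n = s.size
    for _ in range(config.bootstrap_reps):
        idx = rng.integers(0, n, size=n)
        try:
            res = maxstat_select(s[idx], t[idx], e[idx], config, endpoint)
            counts[res.best_cutoff] += 1
        except NoAdmissibleCutpointError:
            counts["none"] += 1
    freq = {k: v / config.bootstrap_reps for k, v in counts.items()}
    return CutpointResult(
        best_cutoff=full.best_cutoff,
        candidates=full.candidates,
        endpoint=endpoint,
        selection_frequency=freq,
    )
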