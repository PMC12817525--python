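"""Organoid formation potential (OFP) grading.

OFP summarises how vigorously a tumour sample grows ex vivo and is used as a
proxy for residual tumour viability after chemotherapy.  Three grades:

* **OFP-I** (robust): organoids appear within three weeks, form large
  (>100 µm) clusters, show abundant EdU-positive nuclei and sustained growth.
* **OFP-II** (intermediate): organoids form and stay viable but growth and
  proliferation decline; smaller clusters, moderate EdU incorporation.
* **OFP-III** (minimal/non-forming): little or no formation after three
  weeks, or near-absent proliferation.

For outcome stratification the grades collapse to a high-growth group
(OFP-I) versus a low-growth group (OFP-II/III).

The published grade definitions are qualitative ("abundant"/"moderate"/
"few" EdU); the quantitative thresholds here are one consistent
operationalisation and are exposed through :class:`OFPThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Optional

__all__ = [
    "OFPGrade",
    "GrowthPotentialGroup",
    "OFPThresholds",
    "DEFAULT_THRESHOLDS",
    "OrganoidCultureObservation",
    "grade_ofp",
    "group_ofp",
]


class OFPGrade(IntEnum):
    I = 1
    II = 2
    III = 3


class GrowthPotentialGroup(str, Enum):
    HIGH = "HIGH"  # OFP-I
    LOW = "LOW"    # OFP-II or OFP-III


@dataclass(frozen=True)
class OFPThresholds:
    """Tunable boundaries of the grading decision tree.

    edu_high / edu_low: EdU-positive fractions separating "abundant" from
    "moderate" and "moderate" from "few" proliferation.  min_diameter_um:
    below this a culture holds only sparse aggregates (grade III).
    robust_diameter_um: grade I requires clusters larger than this.
    formation_deadline_days: the three-week window.
    """

    edu_high: float = 0.40
    edu_low: float = 0.05
    min_diameter_um: float = 30.0
    robust_diameter_um: float = 100.0
    formation_deadline_days: float = 21.0


DEFAULT_THRESHOLDS = OFPThresholds()


@dataclass(frozen=True)
class OrganoidCultureObservation:
    """Culture kinetics and proliferation features for one sample.

    ``days_to_formation`` is ``None`` when no organoid emerged within the
    observation window.  ``cluster_diameter_um`` and
    ``edu_positive_fraction`` may be ``None`` only for non-forming cultures.
    """

    days_to_formation: Optional[float]
    cluster_diameter_um: Optional[float] = None
    edu_positive_fraction: Optional[float] = None
    observation_window_days: float = 28.0
    viable_after_3wk: bool = True
    growth_sustained: bool = False

    def __post_init__(self) -> None:
        if self.days_to_formation is not None:
            if self.days_to_formation < 0:
                raise ValueError("days_to_formation must be >= 0")
            if self.days_to_formation > self.observation_window_days:
                raise ValueError(
                    "days_to_formation exceeds the observation window; "
                    "use None for cultures that never formed"
                )
        if self.cluster_diameter_um is not None and self.cluster_diameter_um < 0:
            raise ValueError("cluster_diameter_um must be >= 0")
        if self.edu_positive_fraction is not None and not 0.0 <= self.edu_positive_fraction <= 1.0:
            raise ValueError("edu_positive_fraction must lie in [0, 1]")


def grade_ofp(
    obs: OrganoidCultureObservation,
    thresholds: OFPThresholds = DEFAULT_THRESHOLDS,
) -> OFPGrade:
    """Assign the OFP grade from culture observations.

    Decision tree (proliferation dominates when features conflict, since OFP
    is a proliferation metric):

    1. **III** if no formation within the three-week window, or the culture
       is not viable after three weeks, or EdU / diameter fall below the
       minimal-proliferation floor.
    2. **I** if formation within three weeks with diameter above the robust
       bound, abundant EdU, and sustained growth.
    3. **II** otherwise.
    """
    formed_in_window = (
        obs.days_to_formation is not None
        and obs.days_to_formation <= thresholds.formation_deadline_days
    )
    if not formed_in_window or not obs.viable_after_3wk:
        return OFPGrade.III

    missing = [
        name
        for name, value in (
            ("cluster_diameter_um", obs.cluster_diameter_um),
            ("edu_positive_fraction", obs.edu_positive_fraction),
        )
        if value is None
    ]
    if missing:
        raise ValueError(
            "cannot grade a formed culture with missing features: " + ", ".join(missing)
        )

    if (
        obs.edu_positive_fraction < thresholds.edu_low
        or obs.cluster_diameter_um < thresholds.min_diameter_um
    ):
        return OFPGrade.III
    if (
        obs.cluster_diameter_um > thresholds.robust_diameter_um
        and obs.edu_positive_fraction >= thresholds.edu_high
        and obs.growth_sustained
    ):
        return OFPGrade.I
    return OFPGrade.II


def group_ofp(grade: OFPGrade) -> GrowthPotentialGroup:
    """Collapse grades to the high/low growth-potential dichotomy (I vs II/III)."""
    return GrowthPotentialGroup.HIGH if OFPGrade(grade) is OFPGrade.I else GrowthPotentialGroup.LOW
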