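"""Clinical ground-truth labels: RECIST 1.1, responder binarization, 5-year DFS.

RECIST 1.1 classifies radiological response from the sum of longest
diameters (SLD) of target lesions:

* **CR** — all target lesions vanished (pathologic nodes, if any, shrunk to
  a short axis < 10 mm);
* **PD** — >= 20 % increase in SLD from the nadir AND an absolute rise of
  >= 5 mm, or the appearance of new lesions;
* **PR** — >= 30 % decrease in SLD from baseline;
* **SD** — neither PR-level shrinkage nor PD-level growth.

PD takes precedence over PR when both hold (regrowth after a deep
response).  Responses binarize to responder (CR/PR/SD) versus nonresponder
(PD).  Long-term outcome uses the 5-year disease-free survival benchmark:
relapse before 60 months marks chemoresistant disease, remaining
disease-free at 60 months marks a good response; records censored before
60 months are indeterminate and excluded from accuracy denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Optional

__all__ = [
    "RECISTCategory",
    "RECISTTimepoint",
    "RECISTAssessment",
    "BinaryResponseLabel",
    "FiveYearDFSLabel",
    "Direction",
    "LesionMeasurements",
    "SurvivalRecord",
    "classify_recist",
    "binarize_recist",
    "label_5yr_dfs",
    "recist_ordinal",
    "direction_class",
    "FIVE_YEAR_MONTHS",
]

#: The long-term follow-up benchmark, in months.
FIVE_YEAR_MONTHS = 60.0

# slack for exact-ratio threshold comparisons under binary floating point
_EPS = 1e-9


class RECISTCategory(IntEnum):
    """Four-level response; the integer is the ordinal coding (CR best)."""

    PD = 0
    SD = 1
    PR = 2
    CR = 3


class RECISTTimepoint(str, Enum):
    NAT = "NAT"        # assessed immediately after neoadjuvant therapy
    AT_5Y = "AT_5Y"    # assessed 5 years after curative-intent surgery


@dataclass(frozen=True)
class RECISTAssessment:
    category: RECISTCategory
    timepoint: RECISTTimepoint = RECISTTimepoint.NAT


class BinaryResponseLabel(str, Enum):
    RESPONDER = "RESPONDER"          # CR / PR / SD
    NONRESPONDER = "NONRESPONDER"    # PD


class FiveYearDFSLabel(str, Enum):
    DISEASE_FREE_5Y = "DISEASE_FREE_5Y"
    RECURRENCE_WITHIN_5Y = "RECURRENCE_WITHIN_5Y"
    INDETERMINATE = "INDETERMINATE"  # censored before the benchmark


class Direction(str, Enum):
    IMPROVED = "IMPROVED"
    STABLE = "STABLE"
    WORSENED = "WORSENED"


@dataclass(frozen=True)
class LesionMeasurements:
    """Target-lesion SLD measurements (mm) at baseline, nadir and now."""

    baseline_sld: float
    nadir_sld: float
    current_sld: float
    new_lesions: bool = False
    target_lesions_vanished: bool = False
    pathologic_nodes_short_axis: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("baseline_sld", "nadir_sld", "current_sld"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nadir_sld > self.baseline_sld + _EPS:
            raise ValueError("nadir_sld cannot exceed baseline_sld")


@dataclass(frozen=True)
class SurvivalRecord:
    """Follow-up times (months) with event indicators."""

    dfs_months: float
    dfs_event: bool
    os_months: float
    os_event: bool

    def __post_init__(self) -> None:
        if self.dfs_months < 0 or self.os_months < 0:
            raise ValueError("survival times must be >= 0")
        if self.dfs_event and self.os_event and self.dfs_months > self.os_months + _EPS:
            raise ValueError("dfs_months cannot exceed os_months when both events observed")


def classify_recist(m: LesionMeasurements) -> RECISTCategory:
    """Apply the RECIST 1.1 rules; evaluation order CR -> PD -> PR -> SD.

    Thresholds are evaluated on exact ratios (no rounding before
    comparison).  A zero baseline without the vanished flag leaves the PR
    ratio undefined and raises ``ValueError``.
    """
    if m.target_lesions_vanished:
        nodes_ok = (
            m.pathologic_nodes_short_axis is None
            or m.pathologic_nodes_short_axis < 10.0
        )
        if nodes_ok:
            return RECISTCategory.CR
    if m.baseline_sld == 0:
        raise ValueError(
            "baseline SLD of 0 without vanished target lesions: response ratio undefined"
        )
    growth = m.current_sld - m.nadir_sld
    if m.new_lesions or (
        m.current_sld >= 1.2 * m.nadir_sld - _EPS and growth >= 5.0 - _EPS
    ):
        return RECISTCategory.PD
    if m.current_sld <= 0.7 * m.baseline_sld + _EPS:
        return RECISTCategory.PR
    return RECISTCategory.SD


def binarize_recist(a: RECISTAssessment | RECISTCategory) -> BinaryResponseLabel:
    """Responder (CR/PR/SD) versus nonresponder (PD)."""
    category = a.category if isinstance(a, RECISTAssessment) else RECISTCategory(a)
    if category is RECISTCategory.PD:
        return BinaryResponseLabel.NONRESPONDER
    return BinaryResponseLabel.RESPONDER


def label_5yr_dfs(r: SurvivalRecord, benchmark: float = FIVE_YEAR_MONTHS) -> FiveYearDFSLabel:
    """Dichotomize long-term outcome at the 5-year benchmark (60.0 months inclusive)."""
    if r.dfs_event and r.dfs_months < benchmark:
        return FiveYearDFSLabel.RECURRENCE_WITHIN_5Y
    if r.dfs_months >= benchmark:
        return FiveYearDFSLabel.DISEASE_FREE_5Y
    return FiveYearDFSLabel.INDETERMINATE


def recist_ordinal(category: RECISTCategory) -> int:
    """Ordinal coding CR=3, PR=2, SD=1, PD=0, so that a negative change means
    clinical worsening (and -dRECIST increases with worsening)."""
    return int(RECISTCategory(category))


def direction_class(delta: float) -> Direction:
    """Collapse a signed change (e.g. dCIWS or dRECIST-ordinal) to its direction."""
    if delta > 0:
        return Direction.IMPROVED
    if delta < 0:
        return Direction.WORSENED
    return Direction.STABLE
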