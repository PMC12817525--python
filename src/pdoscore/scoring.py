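"""Per-drug chemosensitivity scoring for osteosarcoma organoids.

Raw readouts are cell inhibition rates (CIR): the percentage of dead cells
in a drug-treated or untreated (control) organoid culture.  The drug's own
contribution is the standardized CIR,

    SCIR = CIR_drug - CIR_control,

the increase in cell killing attributable to the agent.  SCIR maps onto four
ordinal efficacy tiers (- / + / ++ / +++ worth 0..3), and the tier values of
the four core MAPI-regimen drugs (doxorubicin, cisplatin, methotrexate,
ifosfamide) sum to the cell inhibition weighted score (CIWS, 0-12).  A
culture is called SENSITIVE when CIWS >= 5, RESISTANT otherwise.
Carboplatin is assayed and tiered but never enters CIWS.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Drug",
    "MAPI_REGIMEN",
    "EfficacyTier",
    "Sensitivity",
    "DrugAssayResult",
    "SCIRProfile",
    "CIWSResult",
    "SENSITIVITY_CUTOFF",
    "TIER_BOUNDS",
    "compute_scir",
    "assign_tier",
    "compute_ciws",
    "delta_ciws",
    "format_score",
    "parse_score",
]


class Drug(str, Enum):
    """The five-drug osteosarcoma screening panel."""

    DOX = "DOX"   # doxorubicin
    CDDP = "CDDP"  # cisplatin
    MTX = "MTX"   # methotrexate
    IFO = "IFO"   # ifosfamide
    CBP = "CBP"   # carboplatin (assayed, excluded from CIWS)


#: The four core drugs whose tiers sum to CIWS.
MAPI_REGIMEN: tuple[Drug, ...] = (Drug.DOX, Drug.CDDP, Drug.MTX, Drug.IFO)

#: Lower bounds (inclusive) of tiers 1, 2, 3 on the SCIR percentage scale.
TIER_BOUNDS: tuple[float, float, float] = (30.0, 60.0, 80.0)

#: A CIWS at or above this value is called SENSITIVE.
SENSITIVITY_CUTOFF: int = 5


class EfficacyTier(IntEnum):
    """Ordinal drug-efficacy tier; the integer value enters the CIWS sum."""

    NOT_EFFECTIVE = 0       # "-"   SCIR < 30
    POSSIBLY_EFFECTIVE = 1  # "+"   30 <= SCIR < 60
    LIKELY_EFFECTIVE = 2    # "++"  60 <= SCIR < 80
    HIGHLY_EFFECTIVE = 3    # "+++" SCIR >= 80

    @property
    def symbol(self) -> str:
        return _TIER_SYMBOLS[int(self)]

    @classmethod
    def from_symbol(cls, symbol: str) -> "EfficacyTier":
        s = symbol.strip().replace("–", "-").replace("−", "-")
        try:
            return cls(_TIER_SYMBOLS.index(s))
        except ValueError:
            raise ValueError(f"unknown efficacy tier symbol: {symbol!r}") from None


_TIER_SYMBOLS = ("-", "+", "++", "+++")


class Sensitivity(str, Enum):
    SENSITIVE = "S"
    RESISTANT = "R"


def _check_pct(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"{name} must lie in [0, 100], got {value}")
    return value


@dataclass(frozen=True)
class DrugAssayResult:
    """Treated/control dead-cell percentages for one drug on one sample."""

    drug: Drug
    cir_treated: float
    cir_control: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug", Drug(self.drug))
        object.__setattr__(self, "cir_treated", _check_pct("cir_treated", self.cir_treated))
        object.__setattr__(self, "cir_control", _check_pct("cir_control", self.cir_control))

    @property
    def scir(self) -> float:
        return compute_scir(self)


def compute_scir(assay: DrugAssayResult) -> float:
    """Standardized cell inhibition rate: treated minus control, clamped to [0, 100].

    Control death exceeding treated death yields 0 rather than a negative
    value: SCIR measures drug-attributable killing, which cannot be negative
    for tier assignment.
    """
    return min(100.0, max(0.0, assay.cir_treated - assay.cir_control))


def assign_tier(scir: float) -> EfficacyTier:
    """Map an SCIR percentage onto its efficacy tier.

    Boundaries are lower-bound inclusive: [0,30) -> 0, [30,60) -> 1,
    [60,80) -> 2, [80,100] -> 3.
    """
    scir = _check_pct("scir", scir)
    tier = 0
    for bound in TIER_BOUNDS:
        if scir >= bound:
            tier += 1
    return EfficacyTier(tier)


@dataclass(frozen=True)
class SCIRProfile:
    """Per-drug SCIR values for one sample."""

    scir: Mapping[Drug, float]

    def __post_init__(self) -> None:
        cleaned = {Drug(d): _check_pct(f"scir[{d}]", v) for d, v in self.scir.items()}
        object.__setattr__(self, "scir", cleaned)

    @classmethod
    def from_assays(cls, assays: Iterable[DrugAssayResult]) -> "SCIRProfile":
        return cls({a.drug: compute_scir(a) for a in assays})

    def tiers(self) -> dict[Drug, EfficacyTier]:
        return {d: assign_tier(v) for d, v in self.scir.items()}


@dataclass(frozen=True)
class CIWSResult:
    """Composite tier-sum score over a drug regimen with its S/R call."""

    score: int
    classification: Sensitivity
    contributing_drugs: tuple[Drug, ...]

    def __str__(self) -> str:
        return f"{format_score(self.score)} ({self.classification.name})"


def compute_ciws(
    profile: SCIRProfile,
    regimen: Sequence[Drug] = MAPI_REGIMEN,
    cutoff: int = SENSITIVITY_CUTOFF,
) -> CIWSResult:
    """Sum the efficacy tiers of ``regimen`` drugs; call SENSITIVE iff >= ``cutoff``.

    Raises ``KeyError`` listing any regimen drug absent from the profile —
    missing assays are never silently imputed.
    """
    regimen = tuple(Drug(d) for d in regimen)
    if len(set(regimen)) != len(regimen):
        raise ValueError("regimen contains duplicate drugs")
    missing = [d.value for d in regimen if d not in profile.scir]
    if missing:
        raise KeyError(f"profile is missing assay results for: {', '.join(missing)}")
    score = sum(int(assign_tier(profile.scir[d])) for d in regimen)
    cls = Sensitivity.SENSITIVE if score >= cutoff else Sensitivity.RESISTANT
    return CIWSResult(score=score, classification=cls, contributing_drugs=regimen)


def delta_ciws(pre: CIWSResult, post: CIWSResult) -> int:
    """Signed change in CIWS from the pre- to the post-treatment sample."""
    if set(pre.contributing_drugs) != set(post.contributing_drugs):
        raise ValueError(
            "pre and post CIWS were computed on different regimens: "
            f"{sorted(d.value for d in pre.contributing_drugs)} vs "
            f"{sorted(d.value for d in post.contributing_drugs)}"
        )
    return post.score - pre.score


def format_score(score: int) -> str:
    """Render an integer CIWS in '5+' notation."""
    return f"{int(score)}+"


def parse_score(text: str | int) -> int:
    """Parse CIWS from either plain-integer or '5+' notation."""
    if isinstance(text, (int, float)):
        value = int(text)
    else:
        value = int(str(text).strip().rstrip("+").strip())
    if value < 0:
        raise ValueError(f"CIWS cannot be negative: {text!r}")
    return value
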