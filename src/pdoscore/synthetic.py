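"""Seeded synthetic osteosarcoma PDO cohorts with known ground truth.

The generator emits tables with the structure the analysis pipeline
consumes — per-sample drug-assay readouts, organoid-culture observations,
lesion measurements, and per-patient survival follow-up — together with
hidden truth columns (latent chemosensitivity class, the configured cutoff
and hazard ratio) available only in truth mode.

Default cohort shape mirrors the study design the pipeline was built for:
23 patients contributing 31 samples (18 pre-treatment, 13 post-treatment,
8 paired).  The latent class drives everything downstream:

* **scores** — each sample draws a target CIWS conditional on its class
  (sensitive: 5 + Binomial(7, 0.25); resistant: min(4, Binomial(8, 0.4))),
  so the class boundary sits exactly at the 4/5 ordinal boundary and the
  ground-truth dichotomization midpoint is 4.5.  The target is decomposed
  into per-drug tiers and each tier realised as an SCIR drawn uniformly
  inside its band, then re-expressed as treated/control inhibition rates.
* **survival** — exponential event times per class with a configurable
  hazard ratio (default 0.2 for sensitive vs resistant), administrative
  censoring at 60 months plus optional uniform early censoring.
* **imaging** — lesion trajectories constructed to realise a
  class-conditional RECIST category by design (self-consistent with the
  classifier in ``outcomes``).
* **organoid culture** — grade-conditional feature draws, with post-
  treatment resistant tumours enriched for robust formation (OFP-I),
  mirroring the adverse-prognosis direction of residual viability.

Paired post-treatment samples can flip from sensitive to resistant with a
configurable probability, emulating acquired chemoresistance under therapy.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .scoring import MAPI_REGIMEN

__all__ = [
    "SimulationConfig",
    "generate_cohort",
    "truth_report",
    "TRUTH_COLUMNS",
    "TruthTamperedError",
]

TRUTH_COLUMNS = ("latent_sensitive", "true_cutoff", "true_hr")

_TIER_BANDS = ((0.0, 29.5), (30.0, 59.5), (60.0, 79.5), (80.0, 100.0))


class TruthTamperedError(RuntimeError):
    """Truth columns were modified after generation (checksum mismatch)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator; defaults are the study conditions.

    Sample counts satisfy ``n_patients = n_pre + n_post - n_paired``.
    Rates are per month; ``hazard_ratio`` applies to the sensitive class
    relative to the resistant baseline, for both DFS and OS.
    """

    n_patients: int = 23
    n_pre: int = 18
    n_post: int = 13
    n_paired: int = 8
    sensitive_prevalence: float = 0.5
    # target-CIWS distributions per latent class
    sensitive_score_trials: int = 7
    sensitive_score_p: float = 0.25
    resistant_score_trials: int = 8
    resistant_score_p: float = 0.4
    # carboplatin (never in CIWS): Beta(a, b) scaled to [0, 100]
    cbp_beta_a: float = 2.0
    cbp_beta_b: float = 4.0
    # spontaneous death in untreated controls, uniform range (%)
    control_cir_range: tuple[float, float] = (2.0, 12.0)
    resistance_acquisition_prob: float = 0.25
    # survival model (exponential), censoring
    baseline_dfs_rate: float = 0.1          # resistant class; median ~7 months
    hazard_ratio: float = 0.2
    os_extra_mean_months: float = 20.0      # OS = DFS + Exp(mean)
    admin_censor_months: float = 60.0
    early_censor_rate: float = 0.0          # fraction with uniform early censoring
    # organoid formation grade probabilities (I, II, III) per latent class
    ofp_probs_sensitive: tuple[float, float, float] = (0.25, 0.30, 0.45)
    ofp_probs_resistant: tuple[float, float, float] = (0.80, 0.10, 0.10)
    # RECIST category probabilities (CR, PR, SD, PD) after therapy, per class
    recist_probs_sensitive: tuple[float, float, float, float] = (0.05, 0.35, 0.55, 0.05)
    recist_probs_resistant: tuple[float, float, float, float] = (0.0, 0.05, 0.35, 0.60)
    baseline_sld_range: tuple[float, float] = (60.0, 120.0)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_patients != self.n_pre + self.n_post - self.n_paired:
            raise ValueError(
                "inconsistent counts: n_patients must equal n_pre + n_post - n_paired"
            )
        if self.n_paired > min(self.n_pre, self.n_post):
            raise ValueError("n_paired cannot exceed min(n_pre, n_post)")
        if not 0 <= self.sensitive_prevalence <= 1:
            raise ValueError("sensitive_prevalence must lie in [0, 1]")
        if self.baseline_dfs_rate <= 0 or self.hazard_ratio <= 0:
            raise ValueError("rates and hazard ratios must be > 0")
        for name in ("ofp_probs_sensitive", "ofp_probs_resistant",
                     "recist_probs_sensitive", "recist_probs_resistant"):
            probs = getattr(self, name)
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"{name} must be a probability vector")

    @classmethod
    def single_timepoint(cls, n: int, **kwargs) -> "SimulationConfig":
        """A cohort of ``n`` patients, one pre-treatment sample each —
        the shape used by cutpoint/Cox parameter-recovery studies."""
        return cls(n_patients=n, n_pre=n, n_post=0, n_paired=0, **kwargs)


def _draw_target_ciws(rng: np.random.Generator, sensitive: bool, cfg: SimulationConfig) -> int:
    if sensitive:
        return 5 + int(rng.binomial(cfg.sensitive_score_trials, cfg.sensitive_score_p))
    return min(4, int(rng.binomial(cfg.resistant_score_trials, cfg.resistant_score_p)))


def _compose_tiers(rng: np.random.Generator, target: int, n_drugs: int = 4) -> list[int]:
    """Random composition of ``target`` into ``n_drugs`` tier values 0..3."""
    if not 0 <= target <= 3 * n_drugs:
        raise ValueError(f"target CIWS {target} outside [0, {3 * n_drugs}]")
    tiers = [0] * n_drugs
    for _ in range(target):
        open_slots = [i for i, t in enumerate(tiers) if t < 3]
        tiers[open_slots[rng.integers(0, len(open_slots))]] += 1
    return tiers


def _scir_in_tier(rng: np.random.Generator, tier: int) -> float:
    lo, hi = _TIER_BANDS[tier]
    return float(rng.uniform(lo, hi))


def _lesions_for_category(rng: np.random.Generator, category: str, baseline: float) -> dict:
    """SLD trajectory realising ``category`` under the RECIST 1.1 rules."""
    row = {
        "baseline_sld_mm": baseline,
        "new_lesions": 0,
        "target_lesions_vanished": 0,
    }
    if category == "CR":
        row.update(nadir_sld_mm=0.0, current_sld_mm=0.0, target_lesions_vanished=1)
    elif category == "PR":
        current = baseline * rng.uniform(0.35, 0.68)
        row.update(nadir_sld_mm=current, current_sld_mm=current)
    elif category == "SD":
        current = baseline * rng.uniform(0.75, 1.15)
        row.update(nadir_sld_mm=min(baseline, current), current_sld_mm=current)
    elif category == "PD":
        if rng.uniform() < 0.5:
            current = baseline * rng.uniform(0.8, 1.1)
            row.update(
                nadir_sld_mm=min(baseline, current), current_sld_mm=current, new_lesions=1
            )
        else:
            nadir = baseline * rng.uniform(0.6, 0.9)
            current = nadir * 1.25 + rng.uniform(5.0, 20.0)
            row.update(nadir_sld_mm=nadir, current_sld_mm=current)
    else:  # pragma: no cover
        raise ValueError(category)
    return row


def _ofp_features(rng: np.random.Generator, grade: int) -> dict:
    if grade == 1:
        return dict(
            days_to_formation=float(rng.uniform(5, 15)),
            cluster_diameter_um=float(rng.uniform(105, 180)),
            edu_fraction=float(rng.uniform(0.45, 0.80)),
            viable_after_3wk=1,
            growth_sustained=1,
        )
    if grade == 2:
        return dict(
            days_to_formation=float(rng.uniform(8, 20)),
            cluster_diameter_um=float(rng.uniform(45, 95)),
            edu_fraction=float(rng.uniform(0.12, 0.35)),
            viable_after_3wk=1,
            growth_sustained=0,
        )
    # grade III: mostly never forms; otherwise forms late with scant proliferation
    if rng.uniform() < 0.6:
        days = np.nan
    else:
        days = float(rng.uniform(22, 27))
    return dict(
        days_to_formation=days,
        cluster_diameter_um=float(rng.uniform(5, 25)),
        edu_fraction=float(rng.uniform(0.0, 0.04)),
        viable_after_3wk=0,
        growth_sustained=0,
    )


def _truth_checksum(df: pd.DataFrame) -> str:
    payload = df.loc[:, list(TRUTH_COLUMNS)].to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


def generate_cohort(config: SimulationConfig = SimulationConfig(), truth: bool = True) -> pd.DataFrame:
    """Generate a seeded cohort table, one row per patient x timepoint.

    With ``truth=True`` (default) the table carries the hidden ground-truth
    columns and a checksum in ``DataFrame.attrs`` that
    :func:`truth_report` verifies; with ``truth=False`` an analysis-mode
    table without those columns is returned.  Deterministic for a fixed
    ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # patient roster: 1..n_paired paired, then pre-only, then post-only
    patients = []
    for i in range(cfg.n_patients):
        pid = f"SIM{i + 1:02d}"
        if i < cfg.n_paired:
            tps = ("pre", "post")
        elif i < cfg.n_pre:
            tps = ("pre",)
        else:
            tps = ("post",)
        patients.append((pid, tps))

    recist_cats = ("CR", "PR", "SD", "PD")
    rows = []
    for pid, tps in patients:
        sensitive_pre = bool(rng.uniform() < cfg.sensitive_prevalence)
        sensitive_post = sensitive_pre
        if "post" in tps and sensitive_pre:
            if rng.uniform() < cfg.resistance_acquisition_prob:
                sensitive_post = False

        # outcome-driving class: residual (post) biology where sampled
        outcome_sensitive = sensitive_post if "post" in tps else sensitive_pre

        # survival (per patient)
        rate = cfg.baseline_dfs_rate * (cfg.hazard_ratio if outcome_sensitive else 1.0)
        dfs_raw = float(rng.exponential(1.0 / rate))
        os_raw = dfs_raw + float(rng.exponential(cfg.os_extra_mean_months))
        censor = cfg.admin_censor_months
        if cfg.early_censor_rate > 0 and rng.uniform() < cfg.early_censor_rate:
            censor = float(rng.uniform(0, cfg.admin_censor_months))
        dfs_months = min(dfs_raw, censor)
        os_months = min(os_raw, censor)
        dfs_event = int(dfs_raw < censor)
        os_event = int(os_raw < censor)

        # imaging: response to therapy reflects the pre-treatment biology,
        # the 5-year label reflects the survival outcome
        probs = cfg.recist_probs_sensitive if sensitive_pre else cfg.recist_probs_resistant
        recist_nat = recist_cats[int(rng.choice(4, p=probs))]
        baseline_sld = float(rng.uniform(*cfg.baseline_sld_range))
        lesions = _lesions_for_category(rng, recist_nat, baseline_sld)
        disease_free_5y = (not dfs_event) and dfs_months >= cfg.admin_censor_months
        recist_at5y = "CR" if disease_free_5y else "PD"

        for tp in tps:
            sensitive = sensitive_pre if tp == "pre" else sensitive_post
            target = _draw_target_ciws(rng, sensitive, cfg)
            tiers = _compose_tiers(rng, target, len(MAPI_REGIMEN))
            control = float(rng.uniform(*cfg.control_cir_range))
            row = {
                "patient_id": pid,
                "timepoint": tp,
                "cir_control": control,
            }
            for drug, tier in zip(MAPI_REGIMEN, tiers):
                scir = _scir_in_tier(rng, tier)
                row[f"cir_treated_{drug.value}"] = min(100.0, scir + control)
            cbp_scir = 100.0 * float(rng.beta(cfg.cbp_beta_a, cfg.cbp_beta_b))
            row["cir_treated_CBP"] = min(100.0, cbp_scir + control)

            ofp_probs = cfg.ofp_probs_sensitive if sensitive else cfg.ofp_probs_resistant
            grade = 1 + int(rng.choice(3, p=ofp_probs))
            row.update(_ofp_features(rng, grade))

            row.update(lesions)
            row["recist_nat"] = recist_nat
            row["recist_at5y"] = recist_at5y
            row.update(
                dfs_months=dfs_months,
                dfs_event=dfs_event,
                os_months=os_months,
                os_event=os_event,
            )
            row.update(
                latent_sensitive=int(sensitive),
                true_cutoff=4.5,
                true_hr=cfg.hazard_ratio,
            )
            rows.append(row)

    df = pd.DataFrame(rows)
    df.attrs["truth_mode"] = truth
    if truth:
        df.attrs["truth_checksum"] = _truth_checksum(df)
        return df
    return df.drop(columns=list(TRUTH_COLUMNS))


def truth_report(cohort: pd.DataFrame) -> dict:
    """Ground-truth summary for parameter-recovery tests.

    Requires a truth-mode table; verifies the integrity checksum written at
    generation time and raises :class:`TruthTamperedError` on mismatch.
    """
    missing = [c for c in TRUTH_COLUMNS if c not in cohort.columns]
    if missing or not cohort.attrs.get("truth_mode", False):
        raise ValueError(
            "truth_report requires a truth-mode cohort table "
            f"(missing columns: {missing})"
        )
    expected = cohort.attrs.get("truth_checksum")
    if expected is not None and _truth_checksum(cohort) != expected:
        raise TruthTamperedError("truth columns were modified after generation")
    return {
        "latent_sensitive": dict(
            zip(
                cohort["patient_id"] + ":" + cohort["timepoint"],
                cohort["latent_sensitive"].astype(int),
            )
        ),
        "true_cutoff": float(cohort["true_cutoff"].iloc[0]),
        "true_hr": float(cohort["true_hr"].iloc[0]),
    }
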