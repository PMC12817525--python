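"""End-to-end orchestration: score, grade, label, compare, stratify.

:func:`run_reproduction` consumes a cohort table (one row per
patient x timepoint) and emits the full statistics battery in the standard
reporting order: pre-treatment score vs imaging response, post-treatment
score vs 5-year outcome, imaging itself as predictor of the 5-year
outcome, the paired-correctness head-to-head, directional/rank concordance
on paired samples, and KM/Cox survival stratified by score sensitivity and
by organoid growth group.  Deterministic stages produce byte-identical
text reports for identical input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .concordance import (
    ConcordanceReport,
    DirectionalConcordance,
    PairedCorrectnessComparison,
    RankCorrelationResult,
    concordance_report,
    confusion_from_labels,
    directional_concordance,
    paired_correctness_mcnemar,
    rank_correlations,
)
from .ofp import (
    GrowthPotentialGroup,
    OFPGrade,
    OFPThresholds,
    DEFAULT_THRESHOLDS,
    OrganoidCultureObservation,
    grade_ofp,
    group_ofp,
)
from .outcomes import (
    FiveYearDFSLabel,
    RECISTCategory,
    SurvivalRecord,
    direction_class,
    label_5yr_dfs,
    recist_ordinal,
)
from .scoring import (
    MAPI_REGIMEN,
    Drug,
    SCIRProfile,
    Sensitivity,
    assign_tier,
    compute_ciws,
    format_score,
)
from .survival import CoxResult, GroupSurvivalSummary, cox_binary, mean_survival

__all__ = [
    "score_cohort",
    "grade_cohort_ofp",
    "label_cohort",
    "StratifiedSurvival",
    "ReproductionReport",
    "run_reproduction",
    "reference_report",
]


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], context: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{context}: cohort is missing columns: {', '.join(missing)}")


def score_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Append per-drug tiers, the CIWS integer and the S/R call.

    Accepts either raw ``cir_treated_<DRUG>`` + ``cir_control`` columns or
    pre-computed ``scir_<DRUG>`` columns.
    """
    if df.empty:
        raise ValueError("score_cohort: empty cohort")
    out = df.copy()
    raw = all(f"cir_treated_{d.value}" in df.columns for d in MAPI_REGIMEN)
    pre = all(f"scir_{d.value}" in df.columns for d in MAPI_REGIMEN)
    if raw:
        _require_columns(df, ("cir_control",), "score_cohort")
    elif not pre:
        raise ValueError(
            "score_cohort: need cir_treated_<DRUG>+cir_control or scir_<DRUG> columns "
            f"for {[d.value for d in MAPI_REGIMEN]}"
        )
    scores, calls = [], []
    panel = list(MAPI_REGIMEN) + ([Drug.CBP] if raw and "cir_treated_CBP" in df.columns else [])
    tier_cols: dict[Drug, list[str]] = {d: [] for d in panel}
    for _, row in out.iterrows():
        if raw:
            scir = {
                d: min(100.0, max(0.0, row[f"cir_treated_{d.value}"] - row["cir_control"]))
                for d in panel
            }
        else:
            scir = {d: float(row[f"scir_{d.value}"]) for d in MAPI_REGIMEN}
        profile = SCIRProfile(scir)
        res = compute_ciws(profile)
        scores.append(res.score)
        calls.append(res.classification.value)
        for d in panel:
            tier_cols[d].append(assign_tier(scir[d]).symbol)
    for d in panel:
        out[f"tier_{d.value}"] = tier_cols[d]
    out["ciws"] = scores
    out["ciws_notation"] = [format_score(s) for s in scores]
    out["sensitivity_call"] = calls
    return out


def grade_cohort_ofp(
    df: pd.DataFrame, thresholds: OFPThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Append the organoid formation grade and the high/low growth group."""
    if df.empty:
        raise ValueError("grade_cohort_ofp: empty cohort")
    _require_columns(
        df,
        ("days_to_formation", "cluster_diameter_um", "edu_fraction"),
        "grade_cohort_ofp",
    )
    out = df.copy()
    grades, groups = [], []
    for _, row in out.iterrows():
        days = row["days_to_formation"]
        obs = OrganoidCultureObservation(
            days_to_formation=None if pd.isna(days) else float(days),
            cluster_diameter_um=float(row["cluster_diameter_um"]),
            edu_positive_fraction=float(row["edu_fraction"]),
            viable_after_3wk=bool(row.get("viable_after_3wk", True)),
            growth_sustained=bool(row.get("growth_sustained", False)),
        )
        grade = grade_ofp(obs, thresholds)
        grades.append(grade.name)
        groups.append(group_ofp(grade).value)
    out["ofp_grade"] = grades
    out["growth_group"] = groups
    return out


def label_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Append responder binarizations and the 5-year DFS label."""
    if df.empty:
        raise ValueError("label_cohort: empty cohort")
    _require_columns(df, ("recist_nat", "dfs_months", "dfs_event"), "label_cohort")
    out = df.copy()
    out["responder_nat"] = out["recist_nat"].map(lambda c: int(RECISTCategory[c] != RECISTCategory.PD))
    if "recist_at5y" in out.columns:
        out["responder_at5y"] = out["recist_at5y"].map(
            lambda c: int(RECISTCategory[c] != RECISTCategory.PD)
        )
    labels = []
    for _, row in out.iterrows():
        rec = SurvivalRecord(
            dfs_months=float(row["dfs_months"]),
            dfs_event=bool(row["dfs_event"]),
            os_months=float(row.get("os_months", row["dfs_months"])),
            os_event=bool(row.get("os_event", False)),
        )
        labels.append(label_5yr_dfs(rec).value)
    out["dfs5y_label"] = labels
    return out


@dataclass(frozen=True)
class StratifiedSurvival:
    """Two-group survival comparison for one stratification and endpoint."""

    strata: str                # "ciws" or "ofp"
    endpoint: str              # "DFS" or "OS"
    cox: CoxResult
    mean_arithmetic: GroupSurvivalSummary
    mean_rmst: GroupSurvivalSummary
    group_sizes: tuple[int, int]   # (unfavourable, favourable)


@dataclass(frozen=True)
class ReproductionReport:
    pre_vs_recist_nat: ConcordanceReport
    post_vs_dfs5y: ConcordanceReport
    recist_vs_dfs5y: ConcordanceReport
    paired_correctness: PairedCorrectnessComparison
    directional: Optional[DirectionalConcordance]
    rank: Optional[RankCorrelationResult]
    survival: tuple[StratifiedSurvival, ...]
    n_indeterminate_excluded: int = 0
    recovery: Optional[dict] = None   # truth-mode ground-truth echo

    def to_text(self) -> str:
        def pct(x: float) -> str:
            return f"{100 * x:.1f}%"

        def ci(pair: tuple[float, float]) -> str:
            return f"95% CI {100 * pair[0]:.1f}-{100 * pair[1]:.1f}"

        lines = []
        for name, rep in (
            ("PDO vs NAT-RECIST (pre-treatment score)", self.pre_vs_recist_nat),
            ("PDO vs AT-RECIST (5y) (post-treatment score)", self.post_vs_dfs5y),
            ("RECIST-NAT vs 5-year outcome", self.recist_vs_dfs5y),
        ):
            k = rep.table.tp + rep.table.tn
            lines.append(
                f"{name}: accuracy {pct(rep.accuracy)} ({k}/{rep.table.n}; {ci(rep.accuracy_ci)}; "
                f"exact binomial P={rep.accuracy_exact_binomial_p:.3f}); "
                f"sens {pct(rep.sensitivity)}, spec {pct(rep.specificity)}, "
                f"PPV {pct(rep.ppv)}, NPV {pct(rep.npv)}, "
                f"balanced acc {pct(rep.balanced_accuracy)}, kappa={rep.kappa:.3f}, "
                f"McNemar P={rep.mcnemar_p:.3f}"
            )
        pc = self.paired_correctness
        lines.append(
            f"Paired correctness: score-only {pc.only_method1_correct} vs "
            f"imaging-only {pc.only_method2_correct} (exact McNemar P={pc.exact_mcnemar_p:.3f})"
        )
        if self.directional is not None:
            lines.append(
                f"Directional concordance: {pct(self.directional.agreement)} "
                f"({int(round(self.directional.agreement * self.directional.n))}/"
                f"{self.directional.n}), kappa={self.directional.kappa:.2f}"
            )
        if self.rank is not None:
            lines.append(
                f"Delta correlation: Spearman rho={self.rank.spearman_rho:.3f} "
                f"(P={self.rank.spearman_p:.3f}), Kendall tau-b={self.rank.kendall_tau_b:.3f} "
                f"(P={self.rank.kendall_p:.3f})"
            )
        for s in self.survival:
            flag = " [unstable: <5 events/group]" if s.cox.unstable else ""
            lines.append(
                f"{s.strata.upper()} strata, {s.endpoint}: HR={s.cox.hazard_ratio:.2f} "
                f"(95% CI {s.cox.ci_lower:.2f}-{s.cox.ci_upper:.2f}); "
                f"log-rank P={s.cox.logrank_p:.3f}; "
                f"mean {s.mean_arithmetic.mean_by_group[1]:.1f} vs "
                f"{s.mean_arithmetic.mean_by_group[0]:.1f} months (arithmetic), "
                f"{s.mean_rmst.mean_by_group[1]:.1f} vs "
                f"{s.mean_rmst.mean_by_group[0]:.1f} (RMST to {s.mean_rmst.horizon:.0f} mo)"
                f"{flag}"
            )
        if self.n_indeterminate_excluded:
            lines.append(
                f"Excluded {self.n_indeterminate_excluded} sample(s) with indeterminate "
                "5-year outcome from accuracy denominators"
            )
        if self.recovery is not None:
            lines.append(
                f"Ground truth (truth mode): cutoff={self.recovery['true_cutoff']}, "
                f"HR={self.recovery['true_hr']}"
            )
        return "\n".join(lines)


def _stratified(df: pd.DataFrame, strata: str, indicator: pd.Series) -> list[StratifiedSurvival]:
    out = []
    g = indicator.to_numpy(dtype=int)
    if len(set(g)) < 2:
        return out  # degenerate stratification: every subject on one side
    for endpoint, tcol, ecol in (("DFS", "dfs_months", "dfs_event"), ("OS", "os_months", "os_event")):
        t = df[tcol].to_numpy(dtype=float)
        e = df[ecol].to_numpy(dtype=bool)
        out.append(
            StratifiedSurvival(
                strata=strata,
                endpoint=endpoint,
                cox=cox_binary(t, e, g),
                mean_arithmetic=mean_survival(t, e, g, method="arithmetic"),
                mean_rmst=mean_survival(t, e, g, method="rmst", horizon=60.0),
                group_sizes=(int((g == 0).sum()), int((g == 1).sum())),
            )
        )
    return out


def run_reproduction(cohort: pd.DataFrame) -> ReproductionReport:
    """Run the full battery on a cohort table.

    Requires the drug-assay, culture, imaging and follow-up columns; raises
    with an enumerated column list otherwise.  Samples whose 5-year outcome
    is indeterminate (censored before 60 months) are excluded from accuracy
    denominators and counted in the report.
    """
    if cohort.empty:
        raise ValueError("run_reproduction: empty cohort, no report produced")
    df = label_cohort(grade_cohort_ofp(score_cohort(cohort)))

    pre = df[df["timepoint"] == "pre"]
    post = df[df["timepoint"] == "post"]
    if pre.empty or post.empty:
        raise ValueError("run_reproduction: need both pre and post timepoint samples")

    # 1. pre-treatment score vs imaging response (positive class = nonresponse)
    rep_pre = concordance_report(
        confusion_from_labels(
            predicted=(pre["sensitivity_call"] == Sensitivity.RESISTANT.value).tolist(),
            truth=(pre["responder_nat"] == 0).tolist(),
        )
    )

    # 2./3. post-treatment score and imaging vs determinate 5-year outcome
    det = post[post["dfs5y_label"] != FiveYearDFSLabel.INDETERMINATE.value]
    n_excluded = len(post) - len(det)
    if det.empty:
        raise ValueError("run_reproduction: no determinate 5-year outcomes in post cohort")
    truth_adverse = (det["dfs5y_label"] == FiveYearDFSLabel.RECURRENCE_WITHIN_5Y.value).tolist()
    ciws_pred = (det["sensitivity_call"] == Sensitivity.RESISTANT.value).tolist()
    recist_pred = (det["responder_nat"] == 0).tolist()
    rep_post = concordance_report(confusion_from_labels(ciws_pred, truth_adverse))
    rep_recist = concordance_report(confusion_from_labels(recist_pred, truth_adverse))

    # 4. paired correctness of the two predictors on the same subjects
    correct_ciws = [p == t for p, t in zip(ciws_pred, truth_adverse)]
    correct_recist = [p == t for p, t in zip(recist_pred, truth_adverse)]
    paired = paired_correctness_mcnemar(correct_ciws, correct_recist)

    # 5. directional and rank concordance on paired pre/post patients
    directional = None
    rank = None
    paired_ids = sorted(set(pre["patient_id"]) & set(post["patient_id"]))
    if len(paired_ids) >= 3:
        d_ciws, d_recist = [], []
        for pid in paired_ids:
            s_pre = int(pre.loc[pre["patient_id"] == pid, "ciws"].iloc[0])
            s_post = int(post.loc[post["patient_id"] == pid, "ciws"].iloc[0])
            row = post.loc[post["patient_id"] == pid].iloc[0]
            r_nat = recist_ordinal(RECISTCategory[row["recist_nat"]])
            r_5y = recist_ordinal(RECISTCategory[row["recist_at5y"]])
            d_ciws.append(s_post - s_pre)
            d_recist.append(r_5y - r_nat)
        directional = directional_concordance(
            [direction_class(d) for d in d_ciws],
            [direction_class(d) for d in d_recist],
        )
        try:
            rank = rank_correlations(d_ciws, d_recist)
        except ValueError:
            rank = None  # constant deltas: correlation undefined on this draw

    # 6. survival stratification on the post cohort (favourable group coded 1)
    surv = _stratified(
        post, "ciws", (post["sensitivity_call"] == Sensitivity.SENSITIVE.value).astype(int)
    )
    surv += _stratified(
        post, "ofp", (post["growth_group"] == GrowthPotentialGroup.LOW.value).astype(int)
    )

    recovery = None
    if cohort.attrs.get("truth_mode", False):
        from .synthetic import truth_report

        tr = truth_report(cohort)
        recovery = {"true_cutoff": tr["true_cutoff"], "true_hr": tr["true_hr"]}

    return ReproductionReport(
        pre_vs_recist_nat=rep_pre,
        post_vs_dfs5y=rep_post,
        recist_vs_dfs5y=rep_recist,
        paired_correctness=paired,
        directional=directional,
        rank=rank,
        survival=tuple(surv),
        n_indeterminate_excluded=n_excluded,
        recovery=recovery,
    )


def reference_report() -> dict:
    """Recompute the concordance battery from the built-in reference counts.

    Every number is derived at call time from the stored 2x2 counts via the
    same functions the pipeline uses on fresh cohorts.
    """
    from . import reference as ref
    from .concordance import exact_mcnemar

    return {
        "pre_nat": concordance_report(ref.PRE_NAT_COUNTS),
        "post_nat": concordance_report(ref.POST_NAT_COUNTS),
        "recist_predictor": concordance_report(ref.RECIST_PREDICTOR_COUNTS),
        "paired_correctness_p": exact_mcnemar(*ref.PAIRED_CORRECTNESS_DISCORDANTS),
        "directional_agreement": ref.DIRECTIONAL_AGREEMENT[0] / ref.DIRECTIONAL_AGREEMENT[1],
    }
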