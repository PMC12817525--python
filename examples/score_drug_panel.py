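"""Score a five-drug organoid panel: SCIR, efficacy tiers, and the CIWS call.

A pre-treatment sample with strong doxorubicin response and a post-treatment
sample from the same patient that has lost sensitivity.
"""

from pdoscore import (
    Drug,
    DrugAssayResult,
    SCIRProfile,
    compute_ciws,
    compute_scir,
    delta_ciws,
)

# treated / control dead-cell percentages per drug (pre-treatment biopsy)
assays = [
    DrugAssayResult(Drug.DOX, cir_treated=92, cir_control=8),   # SCIR 84 -> +++
    DrugAssayResult(Drug.CDDP, cir_treated=52, cir_control=8),  # SCIR 44 -> +
    DrugAssayResult(Drug.MTX, cir_treated=47, cir_control=8),   # SCIR 39 -> +
    DrugAssayResult(Drug.IFO, cir_treated=18, cir_control=8),   # SCIR 10 -> -
    DrugAssayResult(Drug.CBP, cir_treated=30, cir_control=8),   # assayed, not in CIWS
]

profile = SCIRProfile.from_assays(assays)
for drug, scir in profile.scir.items():
    tier = profile.tiers()[drug]
    print(f"{drug.value:>4}: SCIR {scir:5.1f}%  tier {tier.symbol}")

pre = compute_ciws(profile)
print(f"pre-treatment CIWS = {pre.score}+ -> {pre.classification.name}")

post_profile = SCIRProfile(
    {Drug.DOX: 45, Drug.CDDP: 40, Drug.MTX: 35, Drug.IFO: 5, Drug.CBP: 15}
)
post = compute_ciws(post_profile)
print(f"post-treatment CIWS = {post.score}+ -> {post.classification.name}")
print(f"delta CIWS = {delta_ciws(pre, post):+d}  (negative: sensitivity lost under therapy)")
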