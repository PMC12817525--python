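"""The exact concordance battery on the built-in reference confusion counts."""

from pdoscore import concordance_report, exact_mcnemar
from pdoscore.reference import (
    PAIRED_CORRECTNESS_DISCORDANTS,
    POST_NAT_COUNTS,
    PRE_NAT_COUNTS,
)

for name, counts in (("pre-treatment score vs imaging response", PRE_NAT_COUNTS),
                     ("post-treatment score vs 5-year outcome", POST_NAT_COUNTS)):
    r = concordance_report(counts)
    print(f"{name}:")
    print(f"  accuracy {100 * r.accuracy:.1f}% "
          f"(95% CI {100 * r.accuracy_ci[0]:.1f}-{100 * r.accuracy_ci[1]:.1f}; "
          f"exact binomial P={r.accuracy_exact_binomial_p:.3f})")
    print(f"  sens {100 * r.sensitivity:.1f}%  spec {100 * r.specificity:.1f}%  "
          f"kappa={r.kappa:.3f}  McNemar P={r.mcnemar_p:.3f}")

p = exact_mcnemar(*PAIRED_CORRECTNESS_DISCORDANTS)
print(f"score-only vs imaging-only correct (3 vs 1): exact McNemar P={p:.3f}")
print("Intervals are Clopper-Pearson; the positive class is the adverse outcome.")
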