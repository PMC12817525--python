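"""Kaplan-Meier / Cox comparison of score-sensitive vs resistant patients."""

import numpy as np

from pdoscore import cox_binary, km_estimate, mean_survival
from pdoscore.pipeline import score_cohort
from pdoscore.synthetic import SimulationConfig, generate_cohort

df = score_cohort(generate_cohort(SimulationConfig.single_timepoint(80, seed=11)))
t = df["dfs_months"].to_numpy(float)
e = df["dfs_event"].to_numpy(bool)
g = (df["ciws"] >= 5).to_numpy(int)  # 1 = sensitive (favourable)

cox = cox_binary(t, e, g)
print(f"Cox HR (sensitive vs resistant) = {cox.hazard_ratio:.2f} "
      f"(95% CI {cox.ci_lower:.2f}-{cox.ci_upper:.2f}), log-rank P = {cox.logrank_p:.4f}")

for method in ("arithmetic", "rmst"):
    m = mean_survival(t, e, g, method=method, horizon=60)
    print(f"mean DFS ({method:>10}): {m.mean_by_group[1]:.1f} vs "
          f"{m.mean_by_group[0]:.1f} months (delta {m.difference:+.1f})")

curve = km_estimate(t[g == 1], e[g == 1])
print(f"sensitive-group KM survival at 24 months: {curve.survival_at(24):.2f}")
print("HR < 1 with a positive delta: sensitivity calls track longer disease-free survival.")
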