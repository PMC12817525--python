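"""RECIST 1.1 classification from lesion measurements and the 5-year DFS label."""

from pdoscore import (
    LesionMeasurements,
    SurvivalRecord,
    binarize_recist,
    classify_recist,
    label_5yr_dfs,
)

cases = {
    "deep shrinkage (-32%)": LesionMeasurements(baseline_sld=100, nadir_sld=68, current_sld=68),
    "size-stable 76 mm lesion": LesionMeasurements(baseline_sld=76, nadir_sld=76, current_sld=76),
    "regrowth +22% / +11 mm": LesionMeasurements(baseline_sld=100, nadir_sld=50, current_sld=61),
    "new pulmonary lesions": LesionMeasurements(baseline_sld=80, nadir_sld=60, current_sld=60, new_lesions=True),
}
for name, m in cases.items():
    cat = classify_recist(m)
    print(f"{name:>26}: {cat.name}  ({binarize_recist(cat).value})")

early_relapse = SurvivalRecord(dfs_months=3, dfs_event=True, os_months=38, os_event=True)
durable = SurvivalRecord(dfs_months=60, dfs_event=False, os_months=60, os_event=False)
print(f"\nrelapse at 3 months  -> {label_5yr_dfs(early_relapse).value}")
print(f"disease-free at 60 mo -> {label_5yr_dfs(durable).value}")
print("Recurrence within 5 years marks chemoresistant disease.")
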