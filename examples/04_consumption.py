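"""Feeder accounting and the consumption comparison pipeline.

Computes per-cage sucrose consumption (g/cage, g/bee, ug a.i./bee) from the
simulated feeder weighings, screens the data (Tukey fences, Shapiro-Wilk,
Bartlett), then groups treatment means with ANOVA + Scott-Knott letters.
"""

from beetox import (
    bartlett_test,
    consumption_table,
    scott_knott,
    shapiro_wilk,
    tukey_filter,
)
from beetox.simulate import paper_like_scenarios, simulate_bioassay

bioassay = simulate_bioassay(paper_like_scenarios(seed=1)["lambda_cyhalothrin_ingestion"])
table = consumption_table(bioassay, density_g_per_ml=1.0)
print("per-cage totals over 96 h:")
print(table.round(4).to_string(index=False))

values = table["per_bee_g"].to_numpy()
fences = tukey_filter(values)
print(f"\nTukey fences [{fences.lower_fence:.4f}, {fences.upper_fence:.4f}]: "
      f"{len(fences.rejected)} of {len(values)} cages rejected")

w, p_sw = shapiro_wilk(fences.kept)
print(f"Shapiro-Wilk W = {w:.3f}, p = {p_sw:.3f}  (normality ok if p > 0.05)")

groups = {l: sub["per_bee_g"].tolist() for l, sub in table.groupby("treatment_label")}
stat, df, p_b = bartlett_test(groups)
print(f"Bartlett chi2({df}) = {stat:.2f}, p = {p_b:.3f}")

grouping = scott_knott(groups, alpha=0.05)
a = grouping.anova
print(f"\nANOVA F({a.df1},{a.df2}) = {a.F:.2f}, p = {a.p_value:.3g}")
print("Scott-Knott letters (shared letter = statistically homogeneous means):")
for label in sorted(groups, key=lambda l: grouping.means[l], reverse=True):
    print(f"  {label:>15}: mean {grouping.means[label]:.4f} g/bee  {grouping.group_labels[label]}")
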