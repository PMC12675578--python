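"""Fit the quantal log-logistic model and convert LC50 to lethal doses.

Uses the topical-route scenario: LC50 in ug/uL, LD50 per bee via the 1 uL
droplet volume, LD50 per gram via the 0.00677 g mean bee weight.
"""

from beetox import (
    batch_from_bioassay,
    dose_response_table,
    fit_ll2,
    lc50_ci,
    ld50_per_gram,
    ld50_topical,
)
from beetox.simulate import paper_like_scenarios, simulate_bioassay

scenario = paper_like_scenarios(seed=1)["lambda_cyhalothrin_topical"]
bioassay = simulate_bioassay(scenario)

batch = batch_from_bioassay(bioassay, time_h=96.0)
fit = fit_ll2(batch)
lc = lc50_ci(fit)
print(f"ground truth: beta = {scenario.true_beta}, LC50 = {scenario.true_e} ug/uL")
print(f"96-h fit:     beta = {fit.slope_beta:.2f}, "
      f"LC50 = {lc.estimate:.3f} [{lc.lower:.3f}-{lc.upper:.3f}] ug/uL")

ld_bee = ld50_topical(lc, applied_volume_ul=1.0)
ld_g = ld50_per_gram(ld_bee)
print(f"LD50 = {ld_bee.estimate:.3f} ug/bee; "
      f"LD50-weight = {ld_g.estimate:.1f} [{ld_g.lower:.1f}-{ld_g.upper:.1f}] ug/g")

print("\ntime-sliced table (24/48/72/96 h):")
table = dose_response_table(bioassay)
print(table[["time_h", "lc50", "lc50_lo", "lc50_hi", "ld50_bee", "ld50_g"]]
      .round(3).to_string(index=False))
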