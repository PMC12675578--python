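"""Score cages with the Bees' Behavioural Stress Index.

Builds three hand-sized observations, scores each, and shows a full
per-treatment trajectory from a simulated ingestion assay.
"""

from beetox import CageObservation, bsi_from_cage, bsi_trajectory
from beetox.simulate import paper_like_scenarios, simulate_bioassay

# one cage, one time: 5 of 10 bees dead, all 5 survivors paralysed
obs = CageObservation(
    treatment_label="83.3",
    cage_id="cage1",
    time_h=48.0,
    n_initial=10,
    n_dead_cum=5,
    behaviour_counts={"paralysis": 5},
)
score = bsi_from_cage(obs)
print(f"half dead, survivors paralysed: BSI = {score.value:.4f} ({score.band.value})")
# -> 0.5714: the index blends 50% mortality with 1-of-7 categories fully altered

quiet = CageObservation("control", "cage1", 48.0, 10, 0)
print(f"untouched control cage:         BSI = {bsi_from_cage(quiet).value:.4f}"
      f" ({bsi_from_cage(quiet).band.value})")

wiped = CageObservation("1.38", "cage1", 1.0, 10, 10)
print(f"complete mortality at 1 h:      BSI = {bsi_from_cage(wiped).value:.4f}"
      f" ({bsi_from_cage(wiped).band.value})")

# a full trajectory: mean over the 3 cages with its standard error and band
bioassay = simulate_bioassay(paper_like_scenarios(seed=1)["lambda_cyhalothrin_ingestion"])
traj = bsi_trajectory(bioassay, "83.3")
print("\ntop-dose trajectory (mean BSI over 3 cages):")
print(traj[["time_h", "mean_bsi", "se", "band"]].to_string(index=False))
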