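# beetox

Analysis toolkit for acute-toxicity bioassays on bees, built around the
**Bees' Behavioural Stress Index (BSI)** — a composite score that folds
cumulative mortality and sublethal behavioural alteration into a single
number in [0, 1] — plus the complete statistical pipeline such assays use:
product-limit survival curves with log-rank comparisons, quantal log-logistic
LC50/LD50 estimation with the standard unit-conversion rules, and
food-consumption statistics with Scott–Knott means grouping.  A synthetic
bioassay generator makes the whole pipeline runnable and testable without any
external data.

It is written for ecotoxicologists running OECD-style caged-worker tests
(typically 3 cages × 10 bees per treatment, observed at 1, 6, 12, 24, 48, 72
and 96 h) on honey bees or stingless bees such as *Nannotrigona
testaceicornis*, and for anyone who needs the BSI or its surrounding
statistics reproducibly in Python.

## The index

For one cage at one observation time,

```
BSI = (1 − DOrg/100) · (Σ BA)/(BC · 100) + DOrg/100
```

where `DOrg` is the cumulative percent of dead organisms, `BA` the percent of
surviving organisms altered in each of `BC = 7` behavioural categories
(agitation, disorientation, paralysis, prostration, difficulty moving, wing
fluttering, self-cleaning), and a cage with total mortality scores exactly 1.
Scores band into stress levels: < 0.2 none, 0.2–0.4 low, 0.4–0.6 moderate,
0.6–0.8 high, > 0.8 extreme.  See `docs/methods.md` for the conventions the
implementation fixes (cumulative mortality, survivor-based BA, band
boundaries) and for the survival, dose–response and consumption models.

## Worked example

```python
from beetox import CageObservation, bsi_from_cage
from beetox.simulate import paper_like_scenarios, simulate_bioassay
from beetox import km_estimate, logrank_test, subjects_from_bioassay
from beetox import batch_from_bioassay, fit_ll2, lc50_ci

# score a single cage: 5 of 10 bees dead, all survivors paralysed
obs = CageObservation("83.3", "cage1", 48.0, 10, 5, {"paralysis": 5})
s = bsi_from_cage(obs)
print(s.value, s.band.value)          # 0.5714285714285715 moderate

# a full simulated assay on the published ingestion concentration grid
b = simulate_bioassay(paper_like_scenarios(seed=1)["lambda_cyhalothrin_ingestion"])
print(km_estimate(b, "83.3").survival_at(96.0))   # 0.0333...
groups = {l: subjects_from_bioassay(b, l) for l in b.treatment_labels()}
r = logrank_test(groups)
print(round(r.chi2, 1), r.df)         # 183.9 6

fit = fit_ll2(batch_from_bioassay(b, 96.0))
ci = lc50_ci(fit)
print(round(ci.estimate, 1), round(ci.lower, 1), round(ci.upper, 1))
# 17.1 11.9 24.5  (ug/mL; the scenario's ground truth LC50 is 19)
```

The cage score 0.571 sits in the moderate band: half the cage is dead and one
of the seven behaviour categories is fully altered among survivors.  The
simulated top dose (83.3 µg/mL) leaves 3% survival at 96 h; comparing all 7
treatment curves gives a log-rank chi-square of 183.9 on 6 df; and the
quantal fit recovers the generator's LC50 (19 µg/mL) within its 95% CI.

The `examples/` directory has one narrative script per capability (stress
index, survival, dose–response, consumption, full report); each prints the
numbers it computes and says what they mean.  A thin CLI wraps the same
library calls:

```
beetox simulate --scenario lambda_cyhalothrin_ingestion --seed 1 --out obs.csv
beetox report --input obs.csv --out-dir report/
```

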