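# Methods

`beetox` analyses acute-toxicity bioassays for bees run in the standard
caged-worker design: each treatment (a pesticide at one concentration via one
exposure route) is replicated in 3 cages of 10 workers, observed at 1, 6, 12,
24, 48, 72 and 96 h after exposure begins.  At each observation the cumulative
number of dead bees is recorded, survivors are scored (non-exclusively) for
seven altered-behaviour categories — agitation, disorientation, paralysis,
prostration, difficulty moving, wing fluttering, self-cleaning — and, for the
ingestion route, the feeder is weighed.  This note records the models, the
conventions the implementation fixes where the field leaves room, and what the
synthetic generator does and does not emulate.

## The behavioural stress index (BSI)

For one cage at one observation time,

    BSI = (1 − DOrg/100) · (Σ BA) / (BC · 100) + DOrg/100

with DOrg the cumulative percent dead, BA the percent altered per behavioural
category, BC = 7 the number of categories.  A cage in which every organism is
dead scores exactly 1.  Two conventions are fixed deliberately:

* **DOrg is cumulative.**  Reading the mortality term as a running sum of
  per-interval death percentages can exceed 100 and pushes the score outside
  [0, 1]; the cumulative reading is the only one consistent with a score
  bounded by 1, and is what the implementation computes.
* **BA is a percentage of current survivors.**  Only survivors can be scored,
  so dividing by survivors keeps every BA ≤ 100 as deaths accumulate and makes
  the all-dead limit continuous.  Percent-of-initial is a conceivable
  alternative; it is not implemented because it drives BA toward 0 as deaths
  rise, double-counting mortality.

With these conventions the index is provably confined to [0, 1], is bounded
below by DOrg/100, is monotone non-decreasing in mortality (∂BSI/∂d = 1 − a ≥ 0)
and strictly increasing in every BA while survivors remain.  The test suite
verifies all of this on a full-factorial grid (mortality in steps of 5, each
BA in steps of 25 — 1.64 million evaluations).

Stress bands: < 0.2 no stress, 0.2–0.4 low, 0.4–0.6 moderate, 0.6–0.8 high,
\> 0.8 extreme.  Bands are closed on the left; the extreme band is open at 0.8
(the one strict inequality in the published banding), so exactly 0.8 is high.

Trajectories summarise per-cage scores: the cage (one colony per cage) is the
replication unit, the mean over cages is reported with its standard error
(sample SD/√n, 0 for a single cage).  A pooled variant (counts summed over
cages before scoring) is available behind a flag; neither is asserted to be
the original authors' choice.

Group contrasts on the BSI use a two-sided permutation test on the difference
of cage means, permuting cage-to-group assignments: with 3 cages per group
there are only 20 assignments, so the p-value is exact by enumeration
(minimum 0.1 at this replication); larger designs fall back to seeded Monte
Carlo with the add-one estimator, so p ≥ 1/(n_perm + 1).  Mixed-model
contrasts are deliberately out of scope; the permutation contrast is the
assumption-light replacement at this replication level.

## Survival

Deaths are interval data — a death is attributed to the observation time at
which it is first recorded, and all deaths at one time are tied.  Bees alive
at 96 h are right-censored there; the fixed-duration design admits no other
censoring.  Analysis pools a treatment's bees across cages (cage-level
frailty is out of scope).

The survival curve is the product-limit estimator with Greenwood standard
errors.  Group comparison is the k-sample log-rank test: observed minus
expected deaths per group across shared event times with the hypergeometric
variance, chi-square with k − 1 df.  Pairwise comparisons adjust all
k(k−1)/2 log-rank p-values jointly by the Benjamini–Hochberg step-up rule.
All three are implemented from first principles and cross-checked in the
test suite against lifelines (curves and test statistics to 1e-8) and
statsmodels (BH on 1000 random vectors).

## Quantal dose–response

Mortality cut at an endpoint time (24/48/72/96 h) is binomial per dose with
the two-parameter log-logistic response

    p(x) = 1 / (1 + exp(−β (ln x − ln e)))

— lower/upper asymptotes fixed at 0 and 1, `e` the LC50 on the dose axis used.
Controls are excluded (Abbott's correction for control mortality is available
behind a flag, off by default).  Estimation is by maximum likelihood on
(β, ln e): start values from the linearised logit regression of the empirical
proportions with a ±0.25-count continuity adjustment, then BFGS with analytic
gradients; the variance-covariance matrix is the inverse observed information.
The fit refuses flat response patterns (non-identifiable) and flags
non-convergence rather than returning silently; quasi-separated designs
(every upper dose saturated) are the typical cause of the latter.

Confidence intervals for the LC50 are delta-method intervals on ln e,
exponentiated — symmetric on the log scale and always positive.  Reference
dose-response packages default to the delta method on the raw scale, which
can produce negative lower limits at small n; the log-scale choice is a
deliberate divergence, and the tests show the two agree with a parametric
bootstrap percentile interval within 10% of log-width at the design scale.

Conversions (all exact linear maps, composing to LC50 × V / w to machine
precision):

* topical LD50 (µg/bee) = LC50 (µg/µL) × applied volume, default 1 µL/bee;
* ingestion LD50 (µg/bee): the model is refitted with the per-treatment mean
  ingested active ingredient (µg/bee, from the consumption module) as the
  dose axis;
* per-gram LD50 (µg/g) = LD50 (µg/bee) / mean bee weight, default 0.00677 g.

At the study's design scale (5 doses × 30 bees, β = 2) the 95% CI covers the
true LC50 in ≥ 90% of 200 seeded replicates and the median relative error of
the LC50 is under 15% (both verified in the suite).

## Consumption

Feeder bookkeeping: consumption over an interval = (weight at interval start,
after any refill) − (weight at interval end, before refill).  Slightly
negative values (evaporation, balance noise — no evaporation controls are
modelled) are clipped to 0 with a warning.  Per-bee consumption divides each
interval by the mean of the alive counts at its endpoints (the midpoint rule;
OECD-style alternatives would change totals by at most the within-interval
mortality share).  Active-ingredient intake = (g/bee ÷ solution density) ×
concentration; density defaults to 1 g/mL and is configurable, since the
sucrose-solution density is rarely reported.

Screening and comparison: Tukey fences at Q1 − 1.5·IQR and Q3 + 1.5·IQR
(closed bounds, quartiles by linear interpolation between order statistics —
the convention is logged because published analyses rarely state one; the
filter is single-pass by contract), Shapiro–Wilk (Royston approximation, via
scipy) and Bartlett checks, one-way fixed-effects ANOVA, then Scott–Knott.

Scott–Knott recursively cuts the ordered treatment means at the ordered
binary split maximising the between-group sum of squares B0, accepting a cut
when λ = [π/(2(π−2))] · B0/σ̂₀² exceeds the chi-square quantile at
k/(π − 2) df, with σ̂₀² = [Σ(ȳᵢ − ȳ)² + ν·s²_ȳ]/(k + ν), s²_ȳ = MSE × mean(1/nᵢ),
ν the ANOVA error df.  The customary chi-square calibration is used;
alternative calibrations exist but change only borderline splits.  Because the
recursion partitions, every treatment gets exactly one letter — unlike
pairwise letter displays, overlapping letter groups cannot occur.  The
implementation is checked against an independently written exhaustive-split
oracle on fixtures of up to 6 groups.

## Synthetic bioassays

The generator draws each cage's 96-h death count binomially from the
log-logistic response (controls: background mortality, default 0.02 over
96 h), then spreads those deaths over the seven observation intervals
multinomially with the scenario's hazard weights.  Simulating the endpoint
first keeps the dose–response ground truth exact at 96 h — the quantity the
quantal fits consume — at the cost of not modelling a continuous-time hazard,
which no downstream analysis needs.  Survivors are flagged per behaviour
category independently with probability expit(intercept + slope·ln(1 + dose/e)
+ time-slope·t); the ln(1 + ·) transform keeps controls well defined.  Feeder
weights start at 5 g, fall by truncated-normal interval consumption
(default 0.03 g/bee/day, CV 0.2), and refill to the start weight below 20%.

Defaults are the study design: 3 cages × 10 bees, the published observation
schedule, water plus solvent controls.  The ready-made scenarios reuse the
published concentration grids per pesticide × route; their slopes and LC50s
are illustrative values chosen once to reproduce the qualitative pattern
(λ-cyhalothrin kills mainly at the top doses, acts fast topically;
fenpyroximate is essentially non-lethal at all tested doses) — they are not
estimates from any dataset, and calibrating them to the deposited raw data is
explicitly out of scope.  The topical slope is kept moderate (1.5) because
that grid has a single concentration near the LC50: a much steeper curve
saturates every upper dose and makes the quantal fit non-identifiable,
unlike the real assay in which the topical LC50 was estimable at every cut
time.

What the generator does **not** emulate: correlation between behaviour
categories, cage- or colony-level heterogeneity, time-varying dose effects on
behaviour beyond the linear time term, evaporation, and any quantitative
agreement with the deposited raw data.  Passing end-to-end tests therefore
demonstrate correctness of the estimators under the stated design and
sampling model, not agreement with the original measurements.

## Numerical and scale choices

* Simulation-based checks use 200 replicates (dose-response recovery,
  mortality calibration) and 300 draws (Bartlett null uniformity), 1000
  resamples for the bootstrap CI comparison — sizes at which the asserted
  tolerances are comfortably outside Monte Carlo noise.
* Permutation contrasts enumerate exhaustively whenever the assignment count
  does not exceed n_perm + 1.
* Band boundaries, fence bounds and BH are exact arithmetic; oracle
  comparisons are at 1e-8 (survival) and 1e-12 (BH).
* Degenerate inputs fail loudly: flat quantal responses, zero-variance
  Shapiro–Wilk input, consumption with no bees alive, non-monotone death
  series — each raises a named error rather than returning a number.

## Known limitations

* Interval-censored survival refinements are out of scope; deaths are placed
  at the observation time of first recording.
* The log-logistic fit covers only the two-parameter form (no 3/4-parameter
  variants, no probit link, no model averaging).
* The BSI permutation contrast has granularity 0.1 at 3 cages per group —
  adequate for flagging extreme separations only.
* Published headline statistics that depend on the deposited raw data
  (overall log-rank chi-squares, consumption F values, LC50 point estimates)
  are reproduced structurally (degrees of freedom, table layout, conversion
  arithmetic), not numerically.
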