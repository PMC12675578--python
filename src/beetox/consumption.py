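"""Feeder-weight accounting and the consumption statistics pipeline.

The ingestion assay tracks a feeder (microtube of 1:1 sucrose solution) per
cage.  At each observation it is weighed; if replenished it is weighed before
and after the refill, so consumption over an interval is

    (weight at interval start, after any refill) − (weight at interval end,
     before any refill).

Slightly negative differences (evaporation, balance noise) are clipped to zero
with a warning — evaporation controls are not modelled.  Per-bee consumption
divides each interval's grams by the mean of the alive counts at the interval's
endpoints; a treatment's active-ingredient intake (µg/bee) multiplies the
ingested volume (grams over solution density) by the diet concentration.

The group comparison follows the classical one-way layout: Tukey-fence outlier
filtering (closed fences at Q1 − 1.5·IQR and Q3 + 1.5·IQR, quartiles by linear
interpolation between order statistics), Shapiro–Wilk normality and Bartlett
homogeneity checks, one-way ANOVA, and Scott–Knott grouping of means into
non-overlapping letter groups.
"""

from __future__ import annotations

import itertools
import math
import string
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bioassay import Bioassay, ExposureRoute, ValidationError

__all__ = [
    "ConsumptionRecord",
    "IntervalConsumption",
    "TukeyFilterResult",
    "AnovaResult",
    "MeansGrouping",
    "interval_consumption",
    "per_bee_consumption",
    "ai_intake",
    "cage_consumption",
    "consumption_table",
    "mean_intake_by_treatment",
    "tukey_filter",
    "one_way_anova",
    "bartlett_test",
    "shapiro_wilk",
    "scott_knott",
]


@dataclass(frozen=True)
class IntervalConsumption:
    t_start_h: float
    t_end_h: float
    consumed_g: float
    clipped: bool = False


@dataclass(frozen=True)
class ConsumptionRecord:
    """Per-cage totals over the assay."""

    treatment_label: str
    cage_id: str
    total_g: float
    per_bee_g: float
    ai_per_bee_ug: float | None = None


@dataclass(frozen=True)
class TukeyFilterResult:
    kept: np.ndarray
    rejected: np.ndarray
    lower_fence: float
    upper_fence: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p_value: float
    mse: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]


@dataclass(frozen=True)
class MeansGrouping:
    """Scott–Knott letter display: a *partition* of the treatments.

    Unlike pairwise letter displays, every treatment carries exactly one
    letter; treatments sharing a letter were not separated by the recursive
    partition.  Letters run a, b, c, … in order of descending mean.
    """

    group_labels: dict[str, str]
    means: dict[str, float]
    anova: AnovaResult


# ---------------------------------------------------------------------------
# feeder bookkeeping


def interval_consumption(
    weights: Sequence[tuple[float, float, float | None]],
) -> list[IntervalConsumption]:
    """Grams consumed per observation interval from feeder weighings.

    ``weights`` is a time-sorted sequence of (time_h, weight_g before refill,
    refill_g or None).  The refill recorded at a time takes effect *after* that
    weighing, so the start weight of the next interval is weight + refill.
    Negative consumption is clipped to 0 with a warning.
    """
    if len(weights) < 2:
        raise ValidationError("need a baseline and at least one later weighing")
    times = [w[0] for w in weights]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValidationError("weighing times must be strictly increasing")
    out = []
    for (t0, w0, refill0), (t1, w1, _) in zip(weights, weights[1:]):
        if w0 is None:
            raise ValidationError(f"missing feeder weight at {t0} h")
        if w1 is None:
            raise ValidationError(f"missing feeder weight at {t1} h")
        start = w0 + (refill0 or 0.0)
        consumed = start - w1
        clipped = False
        if consumed < 0:
            warnings.warn(
                f"negative consumption {consumed:.4f} g over ({t0}, {t1}) h clipped to 0",
                stacklevel=2,
            )
            consumed, clipped = 0.0, True
        out.append(IntervalConsumption(t0, t1, consumed, clipped))
    return out


def per_bee_consumption(
    intervals: Sequence[IntervalConsumption],
    alive_at: Mapping[float, int],
) -> tuple[list[float], float]:
    """Per-interval and total g/bee, dividing by the mean of the alive counts
    at each interval's endpoints.

    Returns (per-interval g/bee list, total g/bee summed over intervals).
    """
    per_interval = []
    for iv in intervals:
        try:
            a0, a1 = alive_at[iv.t_start_h], alive_at[iv.t_end_h]
        except KeyError as exc:
            raise ValidationError(f"missing alive count at {exc.args[0]} h") from exc
        mean_alive = (a0 + a1) / 2.0
        if mean_alive <= 0:
            if iv.consumed_g > 0:
                raise ValidationError(
                    f"nonzero consumption over ({iv.t_start_h}, {iv.t_end_h}) h "
                    "with no bees alive"
                )
            per_interval.append(0.0)
        else:
            per_interval.append(iv.consumed_g / mean_alive)
    return per_interval, float(sum(per_interval))


def ai_intake(
    per_bee_g: float, concentration_ug_per_ml: float, density_g_per_ml: float = 1.0
) -> float:
    """Active-ingredient intake (µg/bee): (grams / density) × concentration."""
    if density_g_per_ml <= 0:
        raise ValueError("solution density must be positive")
    if per_bee_g < 0 or concentration_ug_per_ml < 0:
        raise ValueError("consumption and concentration must be non-negative")
    return (per_bee_g / density_g_per_ml) * concentration_ug_per_ml


def cage_consumption(
    bioassay: Bioassay,
    treatment_label: str,
    cage_id: str,
    density_g_per_ml: float = 1.0,
    until_h: float | None = None,
) -> ConsumptionRecord:
    """Totals for one cage from its observation series (requires feeder data)."""
    series = bioassay.cage_series(treatment_label, cage_id)
    if until_h is not None:
        series = [o for o in series if o.time_h <= until_h]
    weights = []
    alive = {}
    for o in series:
        if o.feeder_weight_g is None:
            raise ValidationError(
                f"missing feeder weight (cage {cage_id!r}, time {o.time_h} h)"
            )
        weights.append((o.time_h, o.feeder_weight_g, o.feeder_refill_g))
        alive[o.time_h] = o.n_survivors
    intervals = interval_consumption(weights)
    _, total_per_bee = per_bee_consumption(intervals, alive)
    total = sum(iv.consumed_g for iv in intervals)
    conc = bioassay.treatment(treatment_label).concentration
    return ConsumptionRecord(
        treatment_label=treatment_label,
        cage_id=cage_id,
        total_g=total,
        per_bee_g=total_per_bee,
        ai_per_bee_ug=ai_intake(total_per_bee, conc, density_g_per_ml),
    )


def consumption_table(
    bioassay: Bioassay, density_g_per_ml: float = 1.0, until_h: float | None = None
) -> pd.DataFrame:
    """Per-cage consumption summary (g/cage, g/bee, µg a.i./bee) for the
    ingestion route."""
    if bioassay.route is not ExposureRoute.INGESTION:
        raise ValidationError("consumption accounting applies to the ingestion route")
    rows = []
    for t in bioassay.treatments:
        for cage in bioassay.cages(t.label):
            rec = cage_consumption(bioassay, t.label, cage, density_g_per_ml, until_h)
            rows.append(
                {
                    "treatment_label": rec.treatment_label,
                    "cage_id": rec.cage_id,
                    "total_g": rec.total_g,
                    "per_bee_g": rec.per_bee_g,
                    "ai_per_bee_ug": rec.ai_per_bee_ug,
                }
            )
    return pd.DataFrame(rows)


def mean_intake_by_treatment(
    bioassay: Bioassay,
    times=(24.0, 48.0, 72.0, 96.0),
    density_g_per_ml: float = 1.0,
) -> dict[float, dict[str, float]]:
    """Mean ingested active ingredient (µg/bee) per treatment up to each cut
    time — the dose axis for ingestion-route LD50 fits."""
    out: dict[float, dict[str, float]] = {}
    for t in times:
        per_treatment: dict[str, float] = {}
        for tr in bioassay.treatments:
            vals = [
                cage_consumption(bioassay, tr.label, c, density_g_per_ml, until_h=t).ai_per_bee_ug
                for c in bioassay.cages(tr.label)
            ]
            per_treatment[tr.label] = float(np.mean(vals))
        out[t] = per_treatment
    return out


# ---------------------------------------------------------------------------
# distribution screening and group comparison


def tukey_filter(values) -> TukeyFilterResult:
    """Tukey-fence outlier filter with closed bounds.

    Keeps values in [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; quartiles use linear
    interpolation between order statistics.  Single pass only: re-filtering the
    kept values recomputes fences and may reject more.  With fewer than 4
    values filtering is refused (everything kept, warning issued).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be a 1-d vector")
    if len(x) < 4:
        warnings.warn("fewer than 4 values: refusing to filter, all kept", stacklevel=2)
        return TukeyFilterResult(
            kept=x.copy(), rejected=np.array([]), lower_fence=-np.inf, upper_fence=np.inf
        )
    q1, q3 = np.percentile(x, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (x >= lo) & (x <= hi)
    return TukeyFilterResult(kept=x[mask], rejected=x[~mask], lower_fence=lo, upper_fence=hi)


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA (df1 = k − 1, df2 = N − k)."""
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValidationError(f"group {k!r} has fewer than 2 values")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df1 = len(arrays) - 1
    df2 = len(all_vals) - len(arrays)
    msb = ss_between / df1
    mse = ss_within / df2
    F = msb / mse if mse > 0 else (0.0 if msb == 0 else np.inf)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return AnovaResult(
        F=float(F),
        df1=df1,
        df2=df2,
        p_value=p,
        mse=float(mse),
        group_means={k: float(v.mean()) for k, v in arrays.items()},
        group_sizes={k: len(v) for k, v in arrays.items()},
    )


def bartlett_test(groups: Mapping[str, Sequence[float]]):
    """Bartlett's homogeneity-of-variances test: (statistic, df = k − 1, p)."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValidationError("Bartlett's test needs ≥2 groups of size ≥2")
    stat, p = stats.bartlett(*arrays)
    return float(stat), len(arrays) - 1, float(p)


def shapiro_wilk(values):
    """Shapiro–Wilk normality test (Royston approximation): (W, p)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValidationError("Shapiro–Wilk requires 3 ≤ n ≤ 5000")
    if np.ptp(x) == 0:
        raise ValidationError("Shapiro–Wilk undefined for zero-variance data")
    w, p = stats.shapiro(x)
    return float(w), float(p)


# Scott-Knott chi-square scaling constant: lambda = pi / (2*(pi - 2)).
_SK_SCALE = math.pi / (2.0 * (math.pi - 2.0))


def _sk_best_split(means: np.ndarray) -> tuple[int, float]:
    """Best ordered binary split of a block of means: (cut index, between-SS).

    The cut at index j puts means[:j+1] in one group.  Means carry equal
    weight, the classical formulation on treatment means.
    """
    k = len(means)
    grand = means.mean()
    best_j, best_b0 = -1, -np.inf
    for j in range(k - 1):
        g1, g2 = means[: j + 1], means[j + 1 :]
        b0 = len(g1) * (g1.mean() - grand) ** 2 + len(g2) * (g2.mean() - grand) ** 2
        if b0 > best_b0:
            best_j, best_b0 = j, b0
    return best_j, float(best_b0)


def scott_knott(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    anova: AnovaResult | None = None,
) -> MeansGrouping:
    """Scott–Knott clustering of treatment means.

    Means are ordered and recursively cut at the ordered binary split
    maximising the between-group sum of squares B0.  A cut is accepted when

        lambda = [pi / (2*(pi-2))] * B0 / sigma0²  >  chi²_{1-alpha}(k/(pi-2))

    with sigma0² = [Σ(mean_i − grand)² + nu·s²_mean] / (k + nu), where s²_mean
    estimates the variance of a treatment mean (MSE × mean(1/n_i)) and nu is
    the ANOVA error df.  The recursion yields a partition, so each treatment
    receives exactly one letter.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    labels = list(groups)
    if len(labels) == 1:
        only = labels[0]
        vals = np.asarray(groups[only], dtype=float)
        return MeansGrouping(
            group_labels={only: "a"},
            means={only: float(vals.mean())},
            anova=None,  # type: ignore[arg-type]
        )
    if anova is None:
        anova = one_way_anova(groups)
    nu = anova.df2
    inv_n = np.mean([1.0 / anova.group_sizes[l] for l in labels])
    s2_mean = anova.mse * inv_n

    means = {l: anova.group_means[l] for l in labels}
    ordered = sorted(labels, key=lambda l: means[l], reverse=True)
    mvec = np.array([means[l] for l in ordered])

    blocks: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        block = mvec[lo:hi]
        k = len(block)
        if k < 2:
            blocks.append((lo, hi))
            return
        j, b0 = _sk_best_split(block)
        sigma0 = (np.sum((block - block.mean()) ** 2) + nu * s2_mean) / (k + nu)
        if sigma0 > 0:
            lam = _SK_SCALE * b0 / sigma0
        else:
            lam = math.inf if b0 > 0 else 0.0
        crit = stats.chi2.ppf(1.0 - alpha, k / (math.pi - 2.0))
        if lam > crit:
            recurse(lo, lo + j + 1)
            recurse(lo + j + 1, hi)
        else:
            blocks.append((lo, hi))

    recurse(0, len(ordered))
    blocks.sort()
    letters = {}
    for letter, (lo, hi) in zip(_letter_sequence(), blocks):
        for l in ordered[lo:hi]:
            letters[l] = letter
    return MeansGrouping(group_labels=letters, means=means, anova=anova)


def _letter_sequence():
    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_lowercase, repeat=size):
            yield "".join(combo)
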