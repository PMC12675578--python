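"""The Bees' Behavioural Stress Index (BSI).

The BSI condenses a cage observation into a single score in [0, 1]:

    BSI = (1 - DOrg/100) * (Σ BA) / (BC * 100) + DOrg/100

where DOrg is the cumulative percentage of dead organisms at the observation
time, BA is the percentage of altered organisms in each of the BC behavioural
categories (BC = 7: agitation, disorientation, paralysis, prostration,
difficulty moving, wing fluttering, self-cleaning), and a cage in which every
organism is dead scores exactly 1.

Two reading conventions are fixed here and logged wherever results are written:

* DOrg is the *cumulative* percent dead at time t.  A running sum of
  per-interval death percentages would exceed 100 and push the score outside
  [0, 1]; the cumulative reading is the only one consistent with a score
  bounded by 1.
* BA is the percentage of *current survivors* altered in each category, which
  keeps every BA ≤ 100 as deaths accumulate and makes the all-dead limit
  continuous (mean alteration contributes nothing when no survivors remain).

The score bands are: < 0.2 no stress; 0.2–0.4 low; 0.4–0.6 moderate; 0.6–0.8
high; > 0.8 extreme.  Bands are closed on the left except the extreme band,
which is open at 0.8 (so exactly 0.8 is still "high").
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .bioassay import BEHAVIOUR_CATEGORIES, Bioassay, CageObservation

__all__ = [
    "StressBand",
    "BsiInputs",
    "BsiScore",
    "compute_bsi",
    "classify_stress",
    "bsi_from_cage",
    "bsi_trajectory",
    "permutation_contrast",
]

N_CATEGORIES = len(BEHAVIOUR_CATEGORIES)


class StressBand(str, Enum):
    NO_STRESS = "no_stress"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    EXTREME = "extreme"


@dataclass(frozen=True)
class BsiInputs:
    """Raw ingredients of one BSI evaluation.

    dorg_pct: cumulative percent dead at the observation time, in [0, 100].
    ba_pct:   percent of survivors altered in each behavioural category.
    bc:       number of behavioural categories (must equal len(ba_pct)).
    """

    dorg_pct: float
    ba_pct: tuple[float, ...]
    bc: int = N_CATEGORIES

    def __post_init__(self) -> None:
        if len(self.ba_pct) != self.bc:
            raise ValueError(
                f"ba_pct has length {len(self.ba_pct)} but bc={self.bc}"
            )
        if not 0 <= self.dorg_pct <= 100:
            raise ValueError(f"dorg_pct={self.dorg_pct} outside [0, 100]")
        for v in self.ba_pct:
            if not 0 <= v <= 100:
                raise ValueError(f"ba_pct entry {v} outside [0, 100]")


@dataclass(frozen=True)
class BsiScore:
    value: float
    band: StressBand


def compute_bsi(dorg_pct, ba_pct, bc: int | None = None):
    """Evaluate the stress index.

    Accepts scalars or numpy arrays: ``ba_pct`` may be shaped ``(..., bc)`` with
    ``dorg_pct`` broadcastable over the leading axes, enabling vectorised grid
    sweeps through the same code path as scalar calls.

    Returns a float for scalar input, an array otherwise.  When every organism
    is dead (dorg_pct = 100) the result is exactly 1 regardless of the
    behaviour percentages.
    """
    scalar = np.isscalar(dorg_pct) and np.ndim(ba_pct) <= 1
    d_pct = np.asarray(dorg_pct, dtype=float)
    ba = np.asarray(ba_pct, dtype=float)
    if ba.ndim == 0:
        raise ValueError("ba_pct must be a vector of category percentages")
    if bc is not None and ba.shape[-1] != bc:
        raise ValueError(f"ba_pct has length {ba.shape[-1]} but bc={bc}")
    n_cat = ba.shape[-1]
    if np.any((d_pct < 0) | (d_pct > 100)):
        raise ValueError("dorg_pct outside [0, 100]")
    if np.any((ba < 0) | (ba > 100)):
        raise ValueError("ba_pct entry outside [0, 100]")
    d = d_pct / 100.0
    a = ba.sum(axis=-1) / (n_cat * 100.0)
    value = (1.0 - d) * a + d
    # the all-dead convention: exactly 1 (the formula already yields it, this
    # guards against any floating residue in (1-d)*a)
    value = np.where(d_pct == 100.0, 1.0, value)
    return float(value) if scalar else value


def classify_stress(value: float) -> StressBand:
    """Map a BSI value to its stress band.

    Bands are lower-closed except extreme, which is open at 0.8:
    [0, 0.2) no stress, [0.2, 0.4) low, [0.4, 0.6) moderate, [0.6, 0.8] high,
    (0.8, 1] extreme.
    """
    if not (0.0 <= value <= 1.0) or not math.isfinite(value):
        raise ValueError(f"BSI value {value} outside [0, 1]")
    if value < 0.2:
        return StressBand.NO_STRESS
    if value < 0.4:
        return StressBand.LOW
    if value < 0.6:
        return StressBand.MODERATE
    if value <= 0.8:
        return StressBand.HIGH
    return StressBand.EXTREME


def bsi_from_cage(obs: CageObservation) -> BsiScore:
    """Score one cage at one time.

    DOrg = 100·dead/initial; BA per category = 100·count/survivors (all zero
    when no survivors remain — the all-dead convention then forces the score
    to 1).
    """
    dorg = 100.0 * obs.n_dead_cum / obs.n_initial
    survivors = obs.n_survivors
    if survivors > 0:
        ba = tuple(
            100.0 * obs.behaviour_count(cat) / survivors for cat in BEHAVIOUR_CATEGORIES
        )
    else:
        ba = (0.0,) * N_CATEGORIES
    value = compute_bsi(dorg, ba)
    return BsiScore(value=value, band=classify_stress(value))


def _pooled_bsi(observations: Sequence[CageObservation]) -> float:
    """BSI from counts pooled across cages (alternative to per-cage averaging)."""
    dead = sum(o.n_dead_cum for o in observations)
    total = sum(o.n_initial for o in observations)
    survivors = total - dead
    dorg = 100.0 * dead / total
    if survivors > 0:
        ba = tuple(
            100.0 * sum(o.behaviour_count(cat) for o in observations) / survivors
            for cat in BEHAVIOUR_CATEGORIES
        )
    else:
        ba = (0.0,) * N_CATEGORIES
    return compute_bsi(dorg, ba)


def bsi_trajectory(
    bioassay: Bioassay, treatment_label: str, pooled: bool = False
) -> pd.DataFrame:
    """Per-time BSI summary for one treatment.

    Returns a data frame with one row per observed time: the per-cage BSI
    values (one column per cage), their mean, the standard error of the mean
    (sample SD/√n_cages, 0 for a single cage) and the stress band of the mean.
    With ``pooled=True`` the mean column instead holds the BSI of the counts
    pooled across cages (SE not defined, reported 0).
    """
    cages = bioassay.cages(treatment_label)
    if not cages:
        raise KeyError(f"treatment {treatment_label!r} has no cages")
    rows = []
    for t in bioassay.observed_times(treatment_label):
        obs_at_t = {o.cage_id: o for o in bioassay.observations_at(treatment_label, t)}
        values = [bsi_from_cage(obs_at_t[c]).value for c in cages if c in obs_at_t]
        if pooled:
            mean = _pooled_bsi(list(obs_at_t.values()))
            se = 0.0
        else:
            mean = float(np.mean(values))
            se = float(np.std(values, ddof=1) / math.sqrt(len(values))) if len(values) > 1 else 0.0
        row = {"time_h": t}
        for c, v in zip(cages, values):
            row[f"bsi_{c}"] = v
        row.update(mean_bsi=mean, se=se, band=classify_stress(mean).value)
        rows.append(row)
    return pd.DataFrame(rows)


def permutation_contrast(
    bioassay: Bioassay,
    treatment_a: str,
    treatment_b: str,
    time_h: float,
    n_perm: int = 9999,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for a difference in mean cage-level BSI.

    Cages are the exchangeable units.  All label assignments are enumerated
    when there are at most ``n_perm + 1`` of them (then the p-value is the
    exact proportion of assignments at least as extreme as the observed one);
    otherwise ``n_perm`` random assignments are drawn and the add-one estimate
    (1 + #extreme)/(n_perm + 1) is returned, so p ≥ 1/(n_perm + 1) always.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    values_a = _cage_bsi_values(bioassay, treatment_a, time_h)
    values_b = _cage_bsi_values(bioassay, treatment_b, time_h)
    if len(values_a) < 2 or len(values_b) < 2:
        raise ValueError(
            "permutation contrast needs at least 2 cages per group "
            f"(got {len(values_a)} and {len(values_b)})"
        )
    pooled = np.asarray(values_a + values_b, dtype=float)
    n_a = len(values_a)
    n = len(pooled)
    observed = abs(pooled[:n_a].mean() - pooled[n_a:].mean())
    tol = 1e-12

    n_total = math.comb(n, n_a)
    if n_total <= n_perm + 1:
        extreme = 0
        idx = np.arange(n)
        for combo in itertools.combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            diff = abs(pooled[mask].mean() - pooled[~mask].mean())
            if diff >= observed - tol:
                extreme += 1
        return extreme / n_total

    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        diff = abs(pooled[perm[:n_a]].mean() - pooled[perm[n_a:]].mean())
        if diff >= observed - tol:
            extreme += 1
    return (1 + extreme) / (n_perm + 1)


def _cage_bsi_values(bioassay: Bioassay, treatment_label: str, time_h: float) -> list[float]:
    obs = bioassay.observations_at(treatment_label, time_h)
    return [bsi_from_cage(o).value for o in obs]
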