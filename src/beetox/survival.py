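"""Product-limit survival estimation and log-rank comparisons.

Deaths are recorded as increments of pooled cumulative counts at the fixed
observation times; all deaths at one observation time are treated as tied.
Bees alive at the end of the assay (96 h by default) are right-censored there —
the fixed-duration design admits no other censoring.  Survival is analysed at
the treatment level, pooling bees across a treatment's cages.

The estimators are implemented from first principles (product-limit with
Greenwood variance; the k-sample log-rank statistic with hypergeometric
variance); an established survival library serves only as an independent
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bioassay import Bioassay, ValidationError

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "PairwiseLogRank",
    "subjects_from_bioassay",
    "km_estimate",
    "km_curve",
    "logrank_test",
    "pairwise_logrank",
    "bh_adjust",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit step function with per-time tallies.

    ``times`` includes every observation time (a time with zero deaths leaves
    the estimate unchanged); ``survival[i] = Π_{j≤i} (1 - deaths[j]/at_risk[j])``.
    ``greenwood_se`` is the Greenwood standard error of the estimate.
    """

    times: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n_start: int

    def survival_at(self, time_h: float) -> float:
        """S(t): the step-function value at (just after) ``time_h``."""
        idx = np.searchsorted(self.times, time_h, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "at_risk": self.at_risk,
                "deaths": self.deaths,
                "survival": self.survival,
                "greenwood_se": self.greenwood_se,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p_value: float


@dataclass(frozen=True)
class PairwiseLogRank:
    """All pairwise log-rank tests with a jointly BH-adjusted p-value matrix."""

    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    chi2: pd.DataFrame


def km_curve(times, deaths, n_start: int) -> SurvivalCurve:
    """Product-limit estimate from pooled death counts at observation times.

    Subjects still alive after the last time are right-censored there.
    """
    times = np.asarray(times, dtype=float)
    deaths = np.asarray(deaths, dtype=int)
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")
    if np.any(deaths < 0) or deaths.sum() > n_start:
        raise ValidationError("death counts must be non-negative and total ≤ n_start")
    at_risk = n_start - np.concatenate(([0], np.cumsum(deaths)[:-1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(at_risk > 0, deaths / np.where(at_risk > 0, at_risk, 1), 0.0)
    survival = np.cumprod(1.0 - frac)
    # Greenwood: Var[S] = S^2 Σ d/(r(r-d))
    denom = at_risk * (at_risk - deaths)
    terms = np.where(denom > 0, deaths / np.where(denom > 0, denom, 1), 0.0)
    var = survival**2 * np.cumsum(terms)
    return SurvivalCurve(
        times=times,
        at_risk=at_risk.astype(int),
        deaths=deaths,
        survival=survival,
        greenwood_se=np.sqrt(var),
        n_start=int(n_start),
    )


def km_estimate(bioassay: Bioassay, treatment_label: str) -> SurvivalCurve:
    """Treatment-level survival curve, pooling bees across the treatment's cages."""
    times, deaths, n_start = _pooled_death_table(bioassay, treatment_label)
    return km_curve(times, deaths, n_start)


def _pooled_death_table(bioassay: Bioassay, treatment_label: str):
    times = [t for t in bioassay.observed_times(treatment_label) if t > 0]
    cages = bioassay.cages(treatment_label)
    n_start = 0
    cum = np.zeros(len(times), dtype=int)
    for cage in cages:
        series = {o.time_h: o for o in bioassay.cage_series(treatment_label, cage)}
        n_start += series[0.0].n_initial
        for i, t in enumerate(times):
            if t not in series:
                raise ValidationError(
                    f"cage {cage!r} of treatment {treatment_label!r} missing time {t} h"
                )
            cum[i] += series[t].n_dead_cum
    deaths = np.diff(np.concatenate(([0], cum)))
    return np.asarray(times, dtype=float), deaths, n_start


def subjects_from_bioassay(bioassay: Bioassay, treatment_label: str):
    """Per-subject (duration, event) arrays: deaths at their recorded times,
    survivors censored at the last observation time."""
    times, deaths, n_start = _pooled_death_table(bioassay, treatment_label)
    durations = []
    events = []
    for t, d in zip(times, deaths):
        durations.extend([t] * int(d))
        events.extend([1] * int(d))
    n_cens = n_start - int(deaths.sum())
    end = times[-1] if len(times) else 0.0
    durations.extend([end] * n_cens)
    events.extend([0] * n_cens)
    return np.asarray(durations, dtype=float), np.asarray(events, dtype=int)


def logrank_test(groups: dict[str, tuple[np.ndarray, np.ndarray]]) -> LogRankResult:
    """k-sample log-rank test on per-group (durations, events) arrays.

    At each distinct event time the observed deaths per group are compared with
    the expectation under the hypergeometric model of tied-death sharing; the
    statistic is the quadratic form of (O − E) with the usual variance matrix,
    referred to chi-square with k − 1 degrees of freedom.
    """
    labels = list(groups)
    k = len(labels)
    if k < 2:
        raise ValidationError("log-rank test needs at least 2 groups")
    for lab in labels:
        if len(groups[lab][0]) == 0:
            raise ValidationError(f"group {lab!r} has zero subjects")
    event_times = np.unique(
        np.concatenate([d[e == 1] for d, e in (groups[l] for l in labels)])
        if any((groups[l][1] == 1).any() for l in labels)
        else np.array([])
    )
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        n_i = np.array(
            [np.sum(groups[l][0] >= t) for l in labels], dtype=float
        )  # at risk just before t
        d_i = np.array(
            [np.sum((groups[l][0] == t) & (groups[l][1] == 1)) for l in labels],
            dtype=float,
        )
        N = n_i.sum()
        D = d_i.sum()
        if N <= 0 or D == 0:
            continue
        O += d_i
        E += D * n_i / N
        if N > 1:
            c = D * (N - D) / (N - 1)
            p = n_i / N
            V += c * (np.diag(p) - np.outer(p, p))
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi2=chi2, df=df, p_value=max(min(p, 1.0), 0.0))


def pairwise_logrank(groups: dict[str, tuple[np.ndarray, np.ndarray]]) -> PairwiseLogRank:
    """All k(k−1)/2 pairwise log-rank tests, BH-adjusted as one family."""
    labels = list(groups)
    k = len(labels)
    if k < 2:
        raise ValidationError("pairwise comparisons need at least 2 groups")
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    raw = []
    chis = []
    for i, j in pairs:
        res = logrank_test({labels[i]: groups[labels[i]], labels[j]: groups[labels[j]]})
        raw.append(res.p_value)
        chis.append(res.chi2)
    adjusted = bh_adjust(np.asarray(raw))
    p_raw = pd.DataFrame(np.nan, index=labels, columns=labels)
    p_adj = pd.DataFrame(np.nan, index=labels, columns=labels)
    chi_m = pd.DataFrame(np.nan, index=labels, columns=labels)
    for (i, j), pr, pa, c in zip(pairs, raw, adjusted, chis):
        a, b = labels[i], labels[j]
        p_raw.loc[a, b] = p_raw.loc[b, a] = pr
        p_adj.loc[a, b] = p_adj.loc[b, a] = pa
        chi_m.loc[a, b] = chi_m.loc[b, a] = c
    return PairwiseLogRank(p_raw=p_raw, p_adjusted=p_adj, chi2=chi_m)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    adj_(i) = min_{j ≥ i} p_(j)·m/j over the ascending order statistics, capped
    at 1 and returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a 1-d vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out
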