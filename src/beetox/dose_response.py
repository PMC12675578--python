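"""Quantal dose–response: two-parameter log-logistic fits and LC50/LD50 reporting.

Mortality at a fixed endpoint (default 96 h, with time-sliced fits at 24/48/72 h)
is modelled as binomial with

    p(x) = 1 / (1 + exp(-beta * (ln x - ln e)))

where ``e`` is the dose at 50% response (the LC50 on whatever dose axis is used)
and ``beta`` the log-dose slope.  The lower/upper asymptotes are fixed at 0 and 1
— the standard quantal default for binary mortality spanning the observed range.
Parameters are estimated by maximum likelihood; the variance-covariance matrix
is the inverse observed information on (beta, ln e), and confidence intervals
for e are delta-method intervals on ln e, exponentiated — which guarantees
positive endpoints (some dose-response packages default to the raw scale
instead; the difference is documented, not hidden).

Unit-conversion rules turn an LC50 into per-bee and per-gram lethal doses:

* topical: LD50 (µg/bee) = LC50 (µg/µL) × applied volume (default 1 µL/bee);
* ingestion: the dose axis is re-expressed as the mean ingested active
  ingredient per bee (µg/bee) and the model refitted on that axis;
* per gram: LD50 (µg/g) = LD50 (µg/bee) / mean bee weight (default 0.00677 g).

Controls (concentration 0) are excluded from fits; Abbott's correction for
control mortality is available behind a flag but off by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .bioassay import Bioassay, ValidationError

__all__ = [
    "DEFAULT_BEE_WEIGHT_G",
    "DEFAULT_APPLIED_VOLUME_UL",
    "NonIdentifiableError",
    "QuantalBatch",
    "Ll2Fit",
    "EstimateCI",
    "Ld50Report",
    "batch_from_bioassay",
    "abbott_correct",
    "fit_ll2",
    "predict_mortality",
    "lc50_ci",
    "ld50_topical",
    "ld50_ingestion",
    "ld50_per_gram",
    "dose_response_table",
]

#: Mean worker-bee fresh weight used for per-gram doses (g/bee).
DEFAULT_BEE_WEIGHT_G = 0.00677
#: Volume of solution deposited per bee in the topical assay (µL/bee).
DEFAULT_APPLIED_VOLUME_UL = 1.0


class NonIdentifiableError(ValidationError):
    """The response pattern carries no information about both parameters."""


@dataclass(frozen=True)
class QuantalBatch:
    """Aggregated quantal responses at one endpoint time.

    ``dose`` may be a concentration (µg/mL or µg/µL) or an ingested amount
    (µg/bee); controls are held out of the batch.
    """

    dose: np.ndarray
    n_exposed: np.ndarray
    n_dead: np.ndarray
    time_h: float
    dose_unit: str = ""

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose, dtype=float)
        n = np.asarray(self.n_exposed, dtype=int)
        y = np.asarray(self.n_dead, dtype=int)
        if not (len(dose) == len(n) == len(y)):
            raise ValidationError("dose, n_exposed and n_dead must have equal length")
        if np.any(dose <= 0):
            raise ValidationError("doses must be strictly positive (controls held separately)")
        if np.any((y < 0) | (y > n)):
            raise ValidationError("n_dead must satisfy 0 ≤ n_dead ≤ n_exposed")
        object.__setattr__(self, "dose", dose)
        object.__setattr__(self, "n_exposed", n)
        object.__setattr__(self, "n_dead", y)


@dataclass(frozen=True)
class Ll2Fit:
    """Two-parameter log-logistic MLE.

    ``vcov`` is the inverse observed information on (beta, ln e).
    """

    slope_beta: float
    lc50_e: float
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    dose_unit: str = ""
    time_h: float = float("nan")

    def predict(self, dose) -> np.ndarray | float:
        return predict_mortality(self, dose)


@dataclass(frozen=True)
class EstimateCI:
    """A point estimate with a two-sided confidence interval."""

    estimate: float
    lower: float
    upper: float
    level: float = 0.95
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.lower <= self.estimate <= self.upper:
            raise ValueError(
                f"interval [{self.lower}, {self.upper}] does not contain {self.estimate}"
            )

    def scaled(self, factor: float, unit: str | None = None) -> "EstimateCI":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return EstimateCI(
            estimate=self.estimate * factor,
            lower=self.lower * factor,
            upper=self.upper * factor,
            level=self.level,
            unit=self.unit if unit is None else unit,
        )

    def divided(self, divisor: float, unit: str | None = None) -> "EstimateCI":
        if divisor <= 0:
            raise ValueError("divisor must be positive")
        return EstimateCI(
            estimate=self.estimate / divisor,
            lower=self.lower / divisor,
            upper=self.upper / divisor,
            level=self.level,
            unit=self.unit if unit is None else unit,
        )


@dataclass(frozen=True)
class Ld50Report:
    """One endpoint-time row of the lethal-dose table."""

    time_h: float
    lc50: EstimateCI
    ld50_per_bee: EstimateCI | None
    ld50_per_gram: EstimateCI | None
    bee_weight_g: float = DEFAULT_BEE_WEIGHT_G
    applied_volume_ul: float = DEFAULT_APPLIED_VOLUME_UL


def batch_from_bioassay(
    bioassay: Bioassay,
    time_h: float,
    include_controls: bool = False,
    abbott: bool = False,
) -> QuantalBatch:
    """Pool each treated group's bees and cut cumulative mortality at ``time_h``.

    With ``abbott=True`` treated mortality is corrected for pooled control
    mortality (Abbott's formula) and re-expressed as rounded counts.
    """
    doses, n_ex, n_dead = [], [], []
    control_p = 0.0
    if abbott:
        c_dead = c_tot = 0
        for t in bioassay.treatments:
            if t.is_control:
                for o in bioassay.observations_at(t.label, time_h):
                    c_dead += o.n_dead_cum
                    c_tot += o.n_initial
        control_p = c_dead / c_tot if c_tot else 0.0
    for t in bioassay.treatments:
        if t.is_control and not include_controls:
            continue
        rows = bioassay.observations_at(t.label, time_h)
        n = sum(o.n_initial for o in rows)
        d = sum(o.n_dead_cum for o in rows)
        if abbott and not t.is_control:
            p = abbott_correct(d / n, control_p)
            d = int(round(p * n))
        doses.append(t.concentration)
        n_ex.append(n)
        n_dead.append(d)
    unit = bioassay.treatments[0].concentration_unit if bioassay.treatments else ""
    return QuantalBatch(
        dose=np.asarray(doses), n_exposed=np.asarray(n_ex), n_dead=np.asarray(n_dead),
        time_h=time_h, dose_unit=unit,
    )


def abbott_correct(p_treated: float, p_control: float) -> float:
    """Abbott's correction: (p_t - p_c)/(1 - p_c), floored at 0."""
    if not 0 <= p_control < 1:
        raise ValueError("control mortality must lie in [0, 1)")
    return max((p_treated - p_control) / (1.0 - p_control), 0.0)


def _nll_grad(theta, lx, n, y):
    beta, m = theta
    eta = beta * (lx - m)
    nll = float(np.sum(n * np.logaddexp(0.0, eta) - y * eta))
    p = special.expit(eta)
    r = n * p - y
    grad = np.array([np.sum(r * (lx - m)), -beta * np.sum(r)])
    return nll, grad


def _observed_information(theta, lx, n, y):
    beta, m = theta
    eta = beta * (lx - m)
    p = special.expit(eta)
    w = n * p * (1.0 - p)
    g1 = lx - m
    g2 = np.full_like(lx, -beta)
    H = np.array(
        [
            [np.sum(w * g1 * g1), np.sum(w * g1 * g2)],
            [np.sum(w * g1 * g2), np.sum(w * g2 * g2)],
        ]
    )
    # curvature of eta itself: d²eta/(dbeta dm) = -1
    s = np.sum(n * p - y)
    H += s * np.array([[0.0, -1.0], [-1.0, 0.0]])
    return H


def fit_ll2(batch: QuantalBatch) -> Ll2Fit:
    """Maximum-likelihood two-parameter log-logistic fit.

    Start values come from the linearised logit regression of the empirical
    proportions (with a ±0.25-count continuity adjustment at 0/100%); the
    optimisation is deterministic.  Non-identifiable patterns (fewer than two
    distinct doses, or a flat response) raise; a fit that fails to converge or
    whose information matrix is not positive definite is returned flagged.
    """
    dose = batch.dose
    n = batch.n_exposed.astype(float)
    y = batch.n_dead.astype(float)
    if len(np.unique(dose)) < 2:
        raise NonIdentifiableError("need at least 2 distinct positive doses")
    props = y / n
    if np.all(y == 0) or np.all(y == n) or np.allclose(props, props[0]):
        raise NonIdentifiableError(
            "response is flat across doses (all-identical mortality); "
            "slope and LC50 are not jointly identifiable"
        )
    lx = np.log(dose)
    # continuity-adjusted empirical logits for start values
    y_adj = np.clip(y, 0.25, n - 0.25)
    z = np.log(y_adj / (n - y_adj))
    slope, intercept = np.polyfit(lx, z, 1)
    if slope <= 0 or not np.isfinite(slope):
        slope = 1.0
    m0 = float(np.clip(-intercept / slope, lx.min() - 5, lx.max() + 5))
    theta0 = np.array([float(slope), m0])

    res = optimize.minimize(
        _nll_grad, theta0, args=(lx, n, y), jac=True, method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    beta, m = res.x
    H = _observed_information(res.x, lx, n, y)
    converged = bool(res.success or np.linalg.norm(res.jac) < 1e-6)
    try:
        vcov = np.linalg.inv(H)
        if not np.all(np.isfinite(vcov)) or vcov[0, 0] <= 0 or vcov[1, 1] <= 0:
            converged = False
    except np.linalg.LinAlgError:
        vcov = np.full((2, 2), np.nan)
        converged = False
    # full binomial log-likelihood including the combinatorial constant
    eta = beta * (lx - m)
    loglik = float(
        np.sum(
            special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
            + y * eta - n * np.logaddexp(0.0, eta)
        )
    )
    return Ll2Fit(
        slope_beta=float(beta),
        lc50_e=float(np.exp(m)),
        vcov=vcov,
        loglik=loglik,
        converged=converged,
        n_obs=len(dose),
        dose_unit=batch.dose_unit,
        time_h=batch.time_h,
    )


def predict_mortality(fit: Ll2Fit, dose):
    """Fitted mortality probability at ``dose`` (scalar or array)."""
    d = np.asarray(dose, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dose must be positive")
    p = special.expit(fit.slope_beta * (np.log(d) - math.log(fit.lc50_e)))
    return float(p) if np.isscalar(dose) else p


def lc50_ci(fit: Ll2Fit, level: float = 0.95) -> EstimateCI:
    """Delta-method confidence interval for the LC50, built on ln e.

    The interval is symmetric on the log scale and therefore always positive.
    Refuses a non-converged fit.
    """
    if not fit.converged:
        raise ValidationError("refusing confidence interval from a non-converged fit")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    m = math.log(fit.lc50_e)
    se = math.sqrt(max(fit.vcov[1, 1], 0.0))
    z = stats.norm.ppf(0.5 + level / 2)
    if se == 0.0:
        lower = upper = fit.lc50_e
    else:
        lower, upper = math.exp(m - z * se), math.exp(m + z * se)
    return EstimateCI(
        estimate=fit.lc50_e,
        lower=min(lower, fit.lc50_e),
        upper=max(upper, fit.lc50_e),
        level=level,
        unit=fit.dose_unit,
    )


def ld50_topical(
    lc50: EstimateCI, applied_volume_ul: float = DEFAULT_APPLIED_VOLUME_UL
) -> EstimateCI:
    """LD50 (µg/bee) for the topical route: LC50 (µg/µL) × applied volume (µL)."""
    if applied_volume_ul <= 0:
        raise ValueError("applied volume must be positive")
    return lc50.scaled(applied_volume_ul, unit="ug/bee")


def ld50_per_gram(
    ld50_per_bee: EstimateCI, bee_weight_g: float = DEFAULT_BEE_WEIGHT_G
) -> EstimateCI:
    """LD50 per gram of bee: LD50 (µg/bee) / mean bee weight (g)."""
    if bee_weight_g <= 0:
        raise ValueError("bee weight must be positive")
    return ld50_per_bee.divided(bee_weight_g, unit="ug/g")


def ld50_ingestion(
    intake_ug_per_bee,
    n_exposed,
    n_dead,
    time_h: float = 96.0,
    level: float = 0.95,
) -> tuple[Ll2Fit, EstimateCI]:
    """LD50 on the ingested-dose axis (mean µg active ingredient per bee).

    Refits the log-logistic model with the per-treatment mean intake as the
    dose; the fitted ``e`` is then directly an LD50 in µg/bee.
    """
    batch = QuantalBatch(
        dose=np.asarray(intake_ug_per_bee, dtype=float),
        n_exposed=np.asarray(n_exposed),
        n_dead=np.asarray(n_dead),
        time_h=time_h,
        dose_unit="ug/bee",
    )
    fit = fit_ll2(batch)
    return fit, lc50_ci(fit, level=level)


def dose_response_table(
    bioassay: Bioassay,
    times=(24.0, 48.0, 72.0, 96.0),
    bee_weight_g: float = DEFAULT_BEE_WEIGHT_G,
    applied_volume_ul: float = DEFAULT_APPLIED_VOLUME_UL,
    intake_ug_per_bee_by_time: dict[float, dict[str, float]] | None = None,
    level: float = 0.95,
    abbott: bool = False,
) -> pd.DataFrame:
    """Time-sliced LC50/LD50 summary (one row per endpoint time).

    Times at which the model is non-identifiable (e.g. no deaths yet) are
    reported with NaNs rather than raised, mirroring a report in which early
    cuts cannot be estimated.  For the topical route LD50/bee and LD50/g come
    from the volume and weight conversions; for the ingestion route LD50/bee
    requires per-treatment mean intakes (µg/bee) supplied via
    ``intake_ug_per_bee_by_time`` (computed by the consumption module).
    """
    from .bioassay import ExposureRoute

    rows = []
    for t in times:
        row: dict = {"time_h": t, "dose_unit": ""}
        for key in (
            "lc50", "lc50_lo", "lc50_hi",
            "ld50_bee", "ld50_bee_lo", "ld50_bee_hi",
            "ld50_g", "ld50_g_lo", "ld50_g_hi",
        ):
            row[key] = np.nan
        try:
            batch = batch_from_bioassay(bioassay, t, abbott=abbott)
            fit = fit_ll2(batch)
            lc = lc50_ci(fit, level=level)
        except (NonIdentifiableError, ValidationError, KeyError) as exc:
            row["note"] = f"not estimable: {exc}"
            rows.append(row)
            continue
        row.update(dose_unit=lc.unit, lc50=lc.estimate, lc50_lo=lc.lower, lc50_hi=lc.upper, note="")
        ld_bee = None
        if bioassay.route is ExposureRoute.TOPICAL:
            ld_bee = ld50_topical(lc, applied_volume_ul)
        elif bioassay.route is ExposureRoute.INGESTION and intake_ug_per_bee_by_time:
            intakes = intake_ug_per_bee_by_time.get(t)
            if intakes:
                labels = [
                    tr.label for tr in bioassay.treatments
                    if not tr.is_control and tr.label in intakes
                ]
                try:
                    dose = [intakes[l] for l in labels]
                    n = [sum(o.n_initial for o in bioassay.observations_at(l, t)) for l in labels]
                    d = [sum(o.n_dead_cum for o in bioassay.observations_at(l, t)) for l in labels]
                    _, ld_bee = ld50_ingestion(dose, n, d, time_h=t, level=level)
                except (NonIdentifiableError, ValidationError) as exc:
                    row["note"] = f"LD50/bee not estimable: {exc}"
        if ld_bee is not None:
            row.update(ld50_bee=ld_bee.estimate, ld50_bee_lo=ld_bee.lower, ld50_bee_hi=ld_bee.upper)
            ld_g = ld50_per_gram(ld_bee, bee_weight_g)
            row.update(ld50_g=ld_g.estimate, ld50_g_lo=ld_g.lower, ld50_g_hi=ld_g.upper)
        rows.append(row)
    return pd.DataFrame(rows)
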