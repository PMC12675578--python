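"""Domain types, CSV input/output and structural validation for cage-level bioassays.

The experimental unit is a cage of worker bees (one colony per cage), observed
repeatedly over a fixed schedule (default 0, 1, 6, 12, 24, 48, 72, 96 h).  At each
observation the cumulative number of dead bees is recorded together with counts of
*survivors* displaying each of seven altered-behaviour categories, and — for the
ingestion route — feeder weights.  Deaths are interval data: a death is attributed
to the observation time at which it is first recorded.

Behaviour counts are non-exclusive: one bee may be counted in several categories
at the same observation (the scoring protocol does not force exclusivity).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "BEHAVIOUR_CATEGORIES",
    "DEFAULT_SCHEDULE",
    "BioassayError",
    "SchemaError",
    "ValidationError",
    "ExposureRoute",
    "Treatment",
    "CageObservation",
    "Bioassay",
    "load_bioassay",
    "write_bioassay",
    "cumulative_mortality",
]

#: The seven behavioural categories scored on survivors.
BEHAVIOUR_CATEGORIES: tuple[str, ...] = (
    "agitation",
    "disorientation",
    "paralysis",
    "prostration",
    "difficulty_moving",
    "wing_fluttering",
    "self_cleaning",
)

#: Default observation schedule in hours.
DEFAULT_SCHEDULE: tuple[float, ...] = (0.0, 1.0, 6.0, 12.0, 24.0, 48.0, 72.0, 96.0)

#: Required CSV columns (canonical names; a schema config may remap).
CSV_COLUMNS: tuple[str, ...] = (
    "pesticide",
    "route",
    "treatment_label",
    "concentration",
    "concentration_unit",
    "cage_id",
    "time_h",
    "n_initial",
    "n_dead_cum",
    *BEHAVIOUR_CATEGORIES,
    "feeder_weight_g",
    "feeder_refill_g",
)

_OPTIONAL_COLUMNS = frozenset({"feeder_weight_g", "feeder_refill_g"})


class BioassayError(ValueError):
    """Base class for bioassay data errors."""


class SchemaError(BioassayError):
    """Input table does not match the expected column schema."""


class ValidationError(BioassayError):
    """Data violates a structural invariant (names the offending cage/time)."""


class ExposureRoute(str, Enum):
    """Pesticide contamination route.

    Concentration units follow the route: µg/mL for ingestion (in the sucrose
    diet) and contact-surface (in the sprayed solution), µg/µL for topical
    application (1 µL droplet on the thorax).
    """

    INGESTION = "ingestion"
    TOPICAL = "topical"
    CONTACT_SURFACE = "contact_surface"

    @property
    def concentration_unit(self) -> str:
        return "ug/uL" if self is ExposureRoute.TOPICAL else "ug/mL"


@dataclass(frozen=True)
class Treatment:
    """One experimental group: a pesticide at a concentration via a route.

    Controls (water or solvent) carry concentration 0.
    """

    pesticide: str
    route: ExposureRoute
    concentration: float
    concentration_unit: str
    label: str

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValidationError(
                f"treatment {self.label!r}: concentration must be non-negative"
            )

    @property
    def is_control(self) -> bool:
        return self.concentration == 0


@dataclass(frozen=True)
class CageObservation:
    """One cage at one observation time.

    ``behaviour_counts`` maps each of the seven category names to the number of
    *survivors* displaying it; counts may overlap across categories but each is
    bounded by the number of survivors.
    """

    treatment_label: str
    cage_id: str
    time_h: float
    n_initial: int
    n_dead_cum: int
    behaviour_counts: Mapping[str, int] = field(default_factory=dict)
    feeder_weight_g: float | None = None
    feeder_refill_g: float | None = None

    def __post_init__(self) -> None:
        where = f"(cage {self.cage_id!r}, time {self.time_h} h)"
        if self.n_initial <= 0:
            raise ValidationError(f"n_initial must be positive {where}")
        if not 0 <= self.n_dead_cum <= self.n_initial:
            raise ValidationError(
                f"n_dead_cum={self.n_dead_cum} outside [0, {self.n_initial}] {where}"
            )
        unknown = set(self.behaviour_counts) - set(BEHAVIOUR_CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown behaviour categories {sorted(unknown)} {where}")
        survivors = self.n_survivors
        for cat, count in self.behaviour_counts.items():
            if not 0 <= count <= survivors:
                raise ValidationError(
                    f"behaviour {cat!r} count {count} exceeds {survivors} survivors {where}"
                )
        for attr in ("feeder_weight_g", "feeder_refill_g"):
            v = getattr(self, attr)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValidationError(f"{attr}={v} must be a non-negative real {where}")

    @property
    def n_survivors(self) -> int:
        return self.n_initial - self.n_dead_cum

    def behaviour_count(self, category: str) -> int:
        return int(self.behaviour_counts.get(category, 0))


@dataclass
class Bioassay:
    """A validated collection of cage observations for one pesticide × route test."""

    pesticide: str
    route: ExposureRoute
    treatments: list[Treatment]
    observations: list[CageObservation]
    replicates_per_treatment: int = 3
    bees_per_cage: int = 10
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE

    def __post_init__(self) -> None:
        self.observations = sorted(
            self.observations, key=lambda o: (o.treatment_label, o.cage_id, o.time_h)
        )
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        labels = [t.label for t in self.treatments]
        if len(labels) != len(set(labels)):
            raise ValidationError("treatment labels must be unique within a bioassay")
        known = set(labels)
        schedule = set(self.schedule)
        series: dict[tuple[str, str], list[CageObservation]] = {}
        for obs in self.observations:
            if obs.treatment_label not in known:
                raise ValidationError(
                    f"observation references undeclared treatment {obs.treatment_label!r}"
                )
            if obs.time_h not in schedule:
                raise ValidationError(
                    f"time {obs.time_h} h not in schedule {sorted(schedule)} "
                    f"(cage {obs.cage_id!r})"
                )
            series.setdefault((obs.treatment_label, obs.cage_id), []).append(obs)
        for (label, cage), rows in series.items():
            rows.sort(key=lambda o: o.time_h)
            if rows[0].time_h != 0 or rows[0].n_dead_cum != 0:
                raise ValidationError(
                    f"series (treatment {label!r}, cage {cage!r}) must start at t=0 "
                    "with n_dead_cum=0"
                )
            for prev, cur in zip(rows, rows[1:]):
                if cur.n_dead_cum < prev.n_dead_cum:
                    raise ValidationError(
                        f"n_dead_cum decreases from {prev.n_dead_cum} to {cur.n_dead_cum} "
                        f"(cage {cage!r}, time {cur.time_h} h)"
                    )
                if cur.n_initial != prev.n_initial:
                    raise ValidationError(
                        f"n_initial changes within series (cage {cage!r}, time {cur.time_h} h)"
                    )

    # -- accessors ----------------------------------------------------------

    def treatment(self, label: str) -> Treatment:
        for t in self.treatments:
            if t.label == label:
                return t
        raise KeyError(f"unknown treatment {label!r}")

    def treatment_labels(self) -> list[str]:
        return [t.label for t in self.treatments]

    def cages(self, treatment_label: str) -> list[str]:
        self.treatment(treatment_label)
        return sorted({o.cage_id for o in self.observations if o.treatment_label == treatment_label})

    def cage_series(self, treatment_label: str, cage_id: str) -> list[CageObservation]:
        rows = [
            o
            for o in self.observations
            if o.treatment_label == treatment_label and o.cage_id == cage_id
        ]
        if not rows:
            raise KeyError(f"no observations for (treatment {treatment_label!r}, cage {cage_id!r})")
        return sorted(rows, key=lambda o: o.time_h)

    def observed_times(self, treatment_label: str) -> list[float]:
        self.treatment(treatment_label)
        return sorted({o.time_h for o in self.observations if o.treatment_label == treatment_label})

    def observations_at(self, treatment_label: str, time_h: float) -> list[CageObservation]:
        rows = [
            o
            for o in self.observations
            if o.treatment_label == treatment_label and o.time_h == time_h
        ]
        if not rows:
            raise KeyError(
                f"treatment {treatment_label!r} has no observation at {time_h} h"
            )
        return rows

    # -- interchange --------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        by_label = {t.label: t for t in self.treatments}
        rows = []
        for o in self.observations:
            t = by_label[o.treatment_label]
            row = {
                "pesticide": self.pesticide,
                "route": self.route.value,
                "treatment_label": o.treatment_label,
                "concentration": t.concentration,
                "concentration_unit": t.concentration_unit,
                "cage_id": o.cage_id,
                "time_h": o.time_h,
                "n_initial": o.n_initial,
                "n_dead_cum": o.n_dead_cum,
            }
            for cat in BEHAVIOUR_CATEGORIES:
                row[cat] = o.behaviour_count(cat)
            row["feeder_weight_g"] = o.feeder_weight_g
            row["feeder_refill_g"] = o.feeder_refill_g
            rows.append(row)
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_bioassay(bioassay: Bioassay, path) -> None:
    """Write a bioassay to the canonical tidy CSV dialect (UTF-8, header row)."""
    bioassay.to_frame().to_csv(path, index=False)


def _apply_schema_config(df: pd.DataFrame, schema_config: Mapping[str, str] | None) -> pd.DataFrame:
    if schema_config:
        # config maps canonical name -> actual column name in the file
        rename = {actual: canonical for canonical, actual in schema_config.items()}
        df = df.rename(columns=rename)
    return df


def load_bioassay(path, schema_config: Mapping[str, str] | str | None = None) -> Bioassay:
    """Load and validate a bioassay from a tidy CSV file.

    Parameters
    ----------
    path:
        CSV file with one row per (cage, time); see ``CSV_COLUMNS``.
    schema_config:
        Optional mapping from canonical column names to the names used in the
        file, or a path to a JSON file holding such a mapping.

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it).
    ValidationError
        If a structural invariant fails (the message names cage and time).
    """
    if isinstance(schema_config, str):
        with open(schema_config) as fh:
            schema_config = json.load(fh)
    df = pd.read_csv(path)
    df = _apply_schema_config(df, schema_config)
    for col in CSV_COLUMNS:
        if col not in df.columns:
            if col in _OPTIONAL_COLUMNS:
                df[col] = None
            else:
                raise SchemaError(f"missing required column {col!r}")
    pesticides = df["pesticide"].unique()
    routes = df["route"].unique()
    if len(pesticides) != 1 or len(routes) != 1:
        raise SchemaError(
            "a bioassay file must hold exactly one pesticide and one route; "
            f"found pesticides={list(pesticides)}, routes={list(routes)}"
        )
    try:
        route = ExposureRoute(routes[0])
    except ValueError as exc:
        raise SchemaError(f"unknown exposure route {routes[0]!r}") from exc

    treatments = []
    for label, sub in df.groupby("treatment_label", sort=False):
        conc = sub["concentration"].unique()
        unit = sub["concentration_unit"].unique()
        if len(conc) != 1 or len(unit) != 1:
            raise ValidationError(
                f"treatment {label!r} has inconsistent concentration metadata"
            )
        treatments.append(
            Treatment(
                pesticide=str(pesticides[0]),
                route=route,
                concentration=float(conc[0]),
                concentration_unit=str(unit[0]),
                label=str(label),
            )
        )

    observations = []
    for _, row in df.iterrows():
        counts = {cat: int(row[cat]) for cat in BEHAVIOUR_CATEGORIES}
        observations.append(
            CageObservation(
                treatment_label=str(row["treatment_label"]),
                cage_id=str(row["cage_id"]),
                time_h=float(row["time_h"]),
                n_initial=int(row["n_initial"]),
                n_dead_cum=int(row["n_dead_cum"]),
                behaviour_counts=counts,
                feeder_weight_g=None if pd.isna(row["feeder_weight_g"]) else float(row["feeder_weight_g"]),
                feeder_refill_g=None if pd.isna(row["feeder_refill_g"]) else float(row["feeder_refill_g"]),
            )
        )
    schedule = tuple(sorted(set(DEFAULT_SCHEDULE) | set(df["time_h"].astype(float))))
    return Bioassay(
        pesticide=str(pesticides[0]),
        route=route,
        treatments=treatments,
        observations=observations,
        schedule=schedule,
    )


def cumulative_mortality(bioassay: Bioassay, treatment_label: str, time_h: float) -> float:
    """Percent of the treatment's bees dead by ``time_h``, pooled across cages.

    Returns ``100 × Σ n_dead_cum / Σ n_initial`` over the treatment's cages.
    Raises ``KeyError`` for an unknown treatment or a time not observed.
    """
    rows = bioassay.observations_at(treatment_label, time_h)
    cages = bioassay.cages(treatment_label)
    seen = {o.cage_id for o in rows}
    if seen != set(cages):
        missing = sorted(set(cages) - seen)
        raise KeyError(
            f"treatment {treatment_label!r} missing cages {missing} at {time_h} h"
        )
    dead = sum(o.n_dead_cum for o in rows)
    total = sum(o.n_initial for o in rows)
    return 100.0 * dead / total
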