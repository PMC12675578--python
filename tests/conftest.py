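from __future__ import annotations

import numpy as np
import pytest

from beetox.bioassay import (
    BEHAVIOUR_CATEGORIES,
    Bioassay,
    CageObservation,
    ExposureRoute,
    Treatment,
)


def make_bioassay(
    deaths,
    behaviours=None,
    n_initial=10,
    times=(0.0, 24.0, 48.0, 96.0),
    route=ExposureRoute.INGESTION,
    concentrations=None,
    feeders=None,
):
    """Build a small bioassay from per-cage cumulative death counts.

    deaths: {treatment_label: [[cum deaths per time] per cage]} — each cage
    series must start with 0 at t=0.
    behaviours: optional {treatment_label: {category: [[count per time] per cage]}}.
    feeders: optional {treatment_label: [[(weight, refill) per time] per cage]}.
    """
    behaviours = behaviours or {}
    feeders = feeders or {}
    if concentrations is None:
        concentrations = {label: float(i) for i, label in enumerate(deaths)}
    treatments = [
        Treatment("testicide", route, concentrations[label], route.concentration_unit, label)
        for label in deaths
    ]
    observations = []
    for label, cages in deaths.items():
        for c, series in enumerate(cages):
            cage_id = f"{label}_c{c + 1}"
            for i, t in enumerate(times):
                counts = {}
                for cat in BEHAVIOUR_CATEGORIES:
                    per_cat = behaviours.get(label, {}).get(cat)
                    counts[cat] = per_cat[c][i] if per_cat else 0
                fw = fr = None
                if label in feeders:
                    fw, fr = feeders[label][c][i]
                observations.append(
                    CageObservation(
                        treatment_label=label,
                        cage_id=cage_id,
                        time_h=t,
                        n_initial=n_initial,
                        n_dead_cum=series[i],
                        behaviour_counts=counts,
                        feeder_weight_g=fw,
                        feeder_refill_g=fr,
                    )
                )
    return Bioassay(
        pesticide="testicide",
        route=route,
        treatments=treatments,
        observations=observations,
        schedule=tuple(times),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
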