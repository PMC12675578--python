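"""Combined analysis report: wires every module into one reproducible bundle."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bsi as bsi_mod
from . import consumption as cons_mod
from . import dose_response as dr_mod
from . import survival as surv_mod
from .bioassay import Bioassay, ExposureRoute, load_bioassay

log = logging.getLogger("beetox")

__all__ = ["RunConfig", "run_report"]


@dataclass
class RunConfig:
    """Options for a full analysis run; every field has a documented default."""

    input_path: str = ""
    output_dir: str = "beetox_report"
    times: tuple[float, ...] = (24.0, 48.0, 72.0, 96.0)
    alpha: float = 0.05
    seed: int = 0
    density_g_per_ml: float = 1.0
    bee_weight_g: float = dr_mod.DEFAULT_BEE_WEIGHT_G
    applied_volume_ul: float = dr_mod.DEFAULT_APPLIED_VOLUME_UL
    n_perm: int = 9999
    filter_outliers: bool = False
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        if "times" in data:
            data["times"] = tuple(data["times"])
        return cls(**data)


def _log_interpretation_flags(config: RunConfig) -> None:
    log.info("BSI convention: DOrg is cumulative percent dead; BA denominator is current survivors")
    log.info("Tukey fences use linear-interpolation quartiles, closed bounds")
    log.info("Solution density assumed %.3f g/mL for a.i. intake", config.density_g_per_ml)
    log.info(
        "LD50 conversions: volume %.3f uL/bee, bee weight %.5f g",
        config.applied_volume_ul,
        config.bee_weight_g,
    )


def run_report(config: RunConfig, bioassay: Bioassay | None = None) -> dict:
    """Run every analysis on one bioassay and write the report bundle.

    Writes tidy CSV tables (survival curves, log-rank tests, BSI trajectories,
    dose-response table, consumption table where applicable) plus a
    machine-readable ``summary.json``; returns the summary dict.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    _log_interpretation_flags(config)
    if bioassay is None:
        bioassay = load_bioassay(config.input_path)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = json.loads(config.to_json())
    cfg.pop("output_dir", None)  # bundle location, not part of the analysis
    summary: dict = {
        "pesticide": bioassay.pesticide,
        "route": bioassay.route.value,
        "config": cfg,
    }

    labels = bioassay.treatment_labels()

    # survival -------------------------------------------------------------
    curves = []
    groups = {}
    for label in labels:
        curve = surv_mod.km_estimate(bioassay, label)
        frame = curve.to_frame()
        frame.insert(0, "treatment_label", label)
        curves.append(frame)
        groups[label] = surv_mod.subjects_from_bioassay(bioassay, label)
    pd.concat(curves, ignore_index=True).to_csv(out / "survival_curves.csv", index=False)
    overall = surv_mod.logrank_test(groups)
    summary["logrank"] = {"chi2": overall.chi2, "df": overall.df, "p_value": overall.p_value}
    if len(labels) >= 3 and overall.p_value < config.alpha:
        pw = surv_mod.pairwise_logrank(groups)
        pw.p_adjusted.to_csv(out / "pairwise_logrank_bh.csv")
        summary["pairwise_logrank_file"] = "pairwise_logrank_bh.csv"

    # BSI -------------------------------------------------------------------
    trajs = []
    final_bands = {}
    for label in labels:
        traj = bsi_mod.bsi_trajectory(bioassay, label)
        traj.insert(0, "treatment_label", label)
        trajs.append(traj)
        final_bands[label] = traj.iloc[-1]["band"]
    pd.concat(trajs, ignore_index=True).to_csv(out / "bsi_trajectories.csv", index=False)
    summary["bsi_final_band"] = final_bands

    # dose-response ----------------------------------------------------------
    treated = [t for t in bioassay.treatments if not t.is_control]
    intake = None
    if bioassay.route is ExposureRoute.INGESTION and _has_feeder_data(bioassay):
        intake = cons_mod.mean_intake_by_treatment(
            bioassay, times=config.times, density_g_per_ml=config.density_g_per_ml
        )
    if len({t.concentration for t in treated}) >= 2:
        try:
            table = dr_mod.dose_response_table(
                bioassay,
                times=config.times,
                bee_weight_g=config.bee_weight_g,
                applied_volume_ul=config.applied_volume_ul,
                intake_ug_per_bee_by_time=intake,
            )
            table.to_csv(out / "dose_response.csv", index=False)
            summary["dose_response"] = {
                "file": "dose_response.csv",
                "lc50_96h": _nan_none(table.loc[table["time_h"] == 96.0, "lc50"]),
            }
        except dr_mod.NonIdentifiableError as exc:
            log.info("dose-response not estimable: %s", exc)
            summary["dose_response"] = {"note": str(exc)}
    else:
        log.info("dose-response skipped: fewer than 2 distinct treated doses")
        summary["dose_response"] = {"note": "skipped: fewer than 2 distinct treated doses"}

    # consumption ------------------------------------------------------------
    if bioassay.route is ExposureRoute.INGESTION and _has_feeder_data(bioassay):
        table = cons_mod.consumption_table(bioassay, density_g_per_ml=config.density_g_per_ml)
        table.to_csv(out / "consumption.csv", index=False)
        per_group = {
            label: sub["per_bee_g"].tolist()
            for label, sub in table.groupby("treatment_label")
        }
        if config.filter_outliers:
            pooled = cons_mod.tukey_filter(table["per_bee_g"].to_numpy())
            per_group = {
                label: [v for v in vals if pooled.lower_fence <= v <= pooled.upper_fence]
                for label, vals in per_group.items()
            }
        usable = {k: v for k, v in per_group.items() if len(v) >= 2}
        if len(usable) >= 2:
            grouping = cons_mod.scott_knott(usable, alpha=config.alpha)
            summary["consumption"] = {
                "file": "consumption.csv",
                "anova": {
                    "F": grouping.anova.F,
                    "df1": grouping.anova.df1,
                    "df2": grouping.anova.df2,
                    "p_value": grouping.anova.p_value,
                },
                "scott_knott_letters": grouping.group_labels,
            }
        else:
            summary["consumption"] = {"file": "consumption.csv", "note": "too few groups for ANOVA"}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _has_feeder_data(bioassay: Bioassay) -> bool:
    return all(o.feeder_weight_g is not None for o in bioassay.observations)


def _nan_none(series) -> float | None:
    if len(series) == 0:
        return None
    v = float(series.iloc[0])
    return None if np.isnan(v) else v
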