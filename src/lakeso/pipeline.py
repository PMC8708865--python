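"""End-to-end orchestration: raw profiles to event table, SEMs and the
trait-regression table.

``build_event_table`` joins, per sampling event (basin x date), the
stratification metrics, the SO index, the diversity indices and the
log-transformed cladoceran biomass.  Events that fail any stage (mixed
water column, fewer than two detectable spectral groups, zero community
biomass, missing zooplankton sample) are excluded with a logged reason —
never silently.

``run_pipeline`` chains simulation (optional), physics, overlap,
diversity, two path models (taxonomic H' and functional F_Dis variants)
and the six permutation trait regressions, and writes all outputs plus
a run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .diversity import community_diversity, gower_dissimilarity, TRAIT_COLUMNS
from .hydrophysics import DepthProfile, stratification_metrics
from .io import DEFAULT_CONFIG, check_genera
from .overlap import SpectralProfileSet, spatial_overlap
from .pathmodel import bootstrap_inference, default_spec, fit_ml
from .synthetic import LakeScenario, StructuralTruth, simulate_lake_dataset
from .traitreg import trait_regression_table

logger = logging.getLogger("lakeso")

__all__ = ["build_event_table", "run_pipeline", "sem_variables"]

EVENT_COLUMNS = [
    "basin",
    "datetime",
    "thermo_depth",
    "meta_upper",
    "meta_lower",
    "meta_width",
    "so",
    "log_cladocera_biom",
    "h_prime",
    "f_dis",
    "cwvar_mld",
    "h_nfix",
    "h_si",
    "h_mix",
    "h_col",
    "h_pig",
]


def _nearest_profile(profiles: Dict, basin: str, dt) -> Optional[DepthProfile]:
    """Profile for the event, preferring an exact key, else nearest in
    time among same-basin profiles with parseable datetimes."""
    if (basin, dt) in profiles:
        return profiles[(basin, dt)]
    target = pd.to_datetime(dt, errors="coerce")
    if pd.isna(target):
        return None
    best, best_delta = None, None
    for (b, t), prof in profiles.items():
        if b != basin:
            continue
        ts = pd.to_datetime(t, errors="coerce")
        if pd.isna(ts):
            continue
        delta = abs(ts - target)
        if best_delta is None or delta < best_delta:
            best, best_delta = prof, delta
    return best


def build_event_table(
    temperature: Dict,
    spectral: Dict,
    biomass: pd.DataFrame,
    traits: pd.DataFrame,
    zoop: pd.DataFrame,
    config: Optional[dict] = None,
):
    """Per-event derived-variable table plus the exclusion log.

    Returns ``(events, exclusions)``: a DataFrame with one row per
    retained event (columns in :data:`EVENT_COLUMNS`) and a DataFrame of
    excluded events with their reasons.  Row accounting is exact:
    ``len(events) + len(exclusions)`` equals the number of candidate
    events.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    check_genera(biomass, traits)
    traits = traits.loc[list(biomass.columns), list(TRAIT_COLUMNS)]
    dissim = gower_dissimilarity(traits)

    rows, excluded = [], []

    def _skip(basin, dt, reason):
        logger.info("excluding event (%s, %s): %s", basin, dt, reason)
        excluded.append({"basin": basin, "datetime": dt, "reason": reason})

    for basin, dt in biomass.index:
        prof = _nearest_profile(temperature, basin, dt)
        if prof is None:
            _skip(basin, dt, "no temperature profile")
            continue
        strat = stratification_metrics(
            prof, threshold=cfg["metalimnion_threshold"], min_gradient=cfg["min_gradient"]
        )
        if not strat.stratified or strat.meta_width is None:
            _skip(basin, dt, "water column not stratified")
            continue
        pset = spectral.get((basin, dt))
        if pset is None:
            _skip(basin, dt, "no spectral profile")
            continue
        ov = spatial_overlap(
            pset,
            n_grid=cfg["n_grid"],
            detection_floor=cfg["detection_floor"],
            absent_as_zero=cfg["absent_as_zero"],
        )
        if ov.so is None:
            _skip(basin, dt, "fewer than two detectable spectral groups")
            continue
        b = biomass.loc[(basin, dt)].to_numpy(float)
        if b.sum() <= 0:
            _skip(basin, dt, "zero community biomass")
            continue
        if (basin, dt) not in zoop.index:
            _skip(basin, dt, "no zooplankton sample")
            continue
        zb = float(zoop.loc[(basin, dt), "biomass_ug_l"])
        if zb <= 0:
            _skip(basin, dt, "non-positive cladoceran biomass (cannot log-transform)")
            continue
        div = community_diversity(b, traits, dissimilarity=dissim)
        rows.append(
            {
                "basin": basin,
                "datetime": dt,
                "thermo_depth": strat.thermo_depth,
                "meta_upper": strat.meta_upper,
                "meta_lower": strat.meta_lower,
                "meta_width": strat.meta_width,
                "so": ov.so,
                "log_cladocera_biom": float(np.log(zb)),
                **asdict(div),
            }
        )
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    exclusions = pd.DataFrame(excluded, columns=["basin", "datetime", "reason"])
    if events.empty:
        raise RuntimeError(
            f"no analyzable events remain ({len(exclusions)} excluded); aborting"
        )
    return events, exclusions


def sem_variables(events: pd.DataFrame, diversity_column: str) -> pd.DataFrame:
    """Rename event-table columns to the path model's variable names."""
    return events.rename(
        columns={
            "thermo_depth": "Thermo_Depth",
            "meta_width": "Meta_Width",
            "log_cladocera_biom": "Cladocera_Biom",
            "so": "SO",
            diversity_column: "Diversity",
        }
    )[["Thermo_Depth", "Meta_Width", "Cladocera_Biom", "SO", "Diversity"]]


def _fit_summary(fit, boot) -> dict:
    return {
        "chisq": fit.chisq,
        "df": fit.df,
        "p": fit.p_value,
        "gfi": fit.gfi,
        "n": fit.n,
        "r2": fit.r_squared,
        "n_boot": boot.n_boot if boot is not None else 0,
        "n_boot_converged": boot.n_converged if boot is not None else 0,
    }


def run_pipeline(config: dict, outdir=None) -> dict:
    """Simulate (seeded), derive the event table, fit both SEMs and the
    trait regressions; write CSV/JSON outputs and a run manifest.

    Returns the result bundle in memory as well.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    outdir = Path(outdir or cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    scenario = LakeScenario(
        n_basins=int(cfg["n_basins"]),
        n_dates=int(cfg["n_dates"]),
        thermo_depth_true=tuple(cfg["thermo_depth_true"]),
        meta_width_true=tuple(cfg["meta_width_true"]),
        noise_sd_temp=float(cfg["noise_sd_temp"]),
        noise_sd_chla=float(cfg["noise_sd_chla"]),
        seed=int(cfg["seed"]),
    )
    logger.info("stage simulate: %d basins x %d dates", scenario.n_basins, scenario.n_dates)
    data = simulate_lake_dataset(scenario)
    zoop = data["zooplankton"].copy()
    zoop["datetime"] = zoop["date"].astype(str)
    zoop = zoop.set_index(["basin", "datetime"])[["biomass_ug_l"]]
    biomass = data["biomass"].copy()
    biomass.index = pd.MultiIndex.from_tuples(
        [(b, str(d)) for b, d in biomass.index], names=["basin", "datetime"]
    )
    temperature = {(b, str(d)): p for (b, d), p in data["temperature"].items()}
    spectral = {(b, str(d)): p for (b, d), p in data["spectral"].items()}

    logger.info("stage physics/overlap/diversity: building event table")
    events, exclusions = build_event_table(
        temperature, spectral, biomass, data["traits"], zoop, cfg
    )
    events.to_csv(outdir / "event_table.csv", index=False)
    exclusions.to_csv(outdir / "exclusions.csv", index=False)

    master = np.random.default_rng(int(cfg["seed"]))
    seeds = master.integers(0, 2**31 - 1, size=3)

    sems = {}
    for label, column in (("h_prime", "h_prime"), ("f_dis", "f_dis")):
        logger.info("stage sem: fitting %s model", label)
        frame = sem_variables(events, column)
        fit = fit_ml(frame, default_spec())
        boot = None
        if int(cfg["n_boot"]) > 0:
            boot = bootstrap_inference(
                frame, default_spec(), n_boot=int(cfg["n_boot"]), seed=int(seeds[0 if label == "h_prime" else 1])
            )
            boot.estimates.reset_index().to_csv(outdir / f"sem_{label}_paths.csv", index=False)
        else:
            fit.estimates.reset_index().to_csv(outdir / f"sem_{label}_paths.csv", index=False)
        summary = _fit_summary(fit, boot)
        with open(outdir / f"sem_{label}.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        sems[label] = {"fit": fit, "bootstrap": boot, "summary": summary}

    logger.info("stage traitreg: %d permutations", int(cfg["n_perm"]))
    table2 = trait_regression_table(events, n_perm=int(cfg["n_perm"]), seed=int(seeds[2]))
    table2.to_csv(outdir / "trait_regressions.csv")

    manifest = {
        "package": "lakeso",
        "version": __version__,
        "seed": int(cfg["seed"]),
        "n_events": int(len(events)),
        "n_excluded": int(len(exclusions)),
        "n_boot": int(cfg["n_boot"]),
        "n_perm": int(cfg["n_perm"]),
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "events": events,
        "exclusions": exclusions,
        "sem": sems,
        "trait_regressions": table2,
        "manifest": manifest,
    }
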