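"""Readers and writers for the pipeline's plain-CSV interchange formats.

All tabular inputs and outputs are uncompressed CSV with documented
headers; every reader validates its schema and reports malformed rows
with their line number in the source file (header = line 1).

Formats
-------
temperature profiles (long)
    ``basin, datetime, depth_m, temp_c``
spectral chlorophyll profiles (long)
    ``basin, datetime, depth_m, chl_browns, chl_greens, chl_cyanos, chl_mixed``
genus biomass matrix (wide)
    ``basin, datetime, <one column per genus>`` (mm3 m-3)
trait matrix
    ``genus, mld, n_fixation, si_fixation, mixotrophy, coloniality, pigment``
    with Y/N for binary traits and level labels for pigment
zooplankton
    ``basin, datetime, biomass_ug_l`` (cladoceran dry biomass, ug L-1)
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import yaml

from .hydrophysics import DepthProfile
from .overlap import SPECTRAL_GROUPS, SpectralProfileSet

__all__ = [
    "read_profiles",
    "read_spectral",
    "read_biomass",
    "read_traits",
    "read_zoop",
    "write_profiles",
    "write_spectral",
    "write_biomass",
    "write_traits",
    "write_zoop",
    "load_config",
    "DEFAULT_CONFIG",
]

EventKey = Tuple[str, str]

SPECTRAL_COLUMNS = tuple(f"chl_{g}" for g in SPECTRAL_GROUPS)
TRAIT_FILE_COLUMNS = ("genus", "mld", "n_fixation", "si_fixation", "mixotrophy", "coloniality", "pigment")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _line(df_index: int) -> int:
    # pandas row i sits on file line i + 2 (header on line 1)
    return int(df_index) + 2


def read_profiles(path) -> Dict[EventKey, DepthProfile]:
    """Temperature profiles keyed by (basin, datetime)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"basin": str, "datetime": str})
    _require_columns(df, ("basin", "datetime", "depth_m", "temp_c"), path)
    bad = df.index[df["temp_c"].isna() | df["depth_m"].isna()]
    if len(bad):
        raise ValueError(f"{path}: non-numeric or missing value on line {_line(bad[0])}")
    out: Dict[EventKey, DepthProfile] = {}
    for (basin, dt), grp in df.groupby(["basin", "datetime"], sort=True):
        grp = grp.sort_values("depth_m")
        if grp["depth_m"].duplicated().any():
            dup = grp.index[grp["depth_m"].duplicated()][0]
            raise ValueError(f"{path}: duplicate depth for event ({basin}, {dt}) on line {_line(dup)}")
        out[(basin, dt)] = DepthProfile(
            grp["depth_m"].to_numpy(float), grp["temp_c"].to_numpy(float), basin=basin, time=dt
        )
    return out


def read_spectral(path) -> Dict[EventKey, SpectralProfileSet]:
    """Four-group chlorophyll profiles keyed by (basin, datetime)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"basin": str, "datetime": str})
    _require_columns(df, ("basin", "datetime", "depth_m") + SPECTRAL_COLUMNS, path)
    for col in SPECTRAL_COLUMNS:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"{path}: missing {col} on line {_line(bad[0])}")
        neg = df.index[df[col] < 0]
        if len(neg):
            raise ValueError(
                f"{path}: negative concentration in {col} on line {_line(neg[0])}"
            )
    out: Dict[EventKey, SpectralProfileSet] = {}
    for (basin, dt), grp in df.groupby(["basin", "datetime"], sort=True):
        grp = grp.sort_values("depth_m")
        out[(basin, dt)] = SpectralProfileSet(
            grp["depth_m"].to_numpy(float),
            {g: grp[f"chl_{g}"].to_numpy(float) for g in SPECTRAL_GROUPS},
            basin=basin,
            time=dt,
        )
    return out


def read_biomass(path) -> pd.DataFrame:
    """Events x genera biomass matrix indexed by (basin, datetime)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"basin": str, "datetime": str})
    _require_columns(df, ("basin", "datetime"), path)
    genera = [c for c in df.columns if c not in ("basin", "datetime")]
    if not genera:
        raise ValueError(f"{path}: no genus columns")
    for col in genera:
        neg = df.index[df[col] < 0]
        if len(neg):
            raise ValueError(f"{path}: negative biomass in {col!r} on line {_line(neg[0])}")
    dup = df.index[df.duplicated(["basin", "datetime"])]
    if len(dup):
        raise ValueError(f"{path}: duplicate event key on line {_line(dup[0])}")
    return df.set_index(["basin", "datetime"])[genera].astype(float)


def read_traits(path) -> pd.DataFrame:
    """Genus x trait matrix indexed by genus."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, TRAIT_FILE_COLUMNS, path)
    dup = df.index[df["genus"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate genus on line {_line(dup[0])}")
    df = df.set_index("genus")
    df["mld"] = pd.to_numeric(df["mld"], errors="coerce")
    bad = df.index[df["mld"].isna() | (df["mld"] <= 0)]
    if len(bad):
        raise ValueError(f"{path}: MLD must be a positive number (genus {bad[0]!r})")
    for col in ("n_fixation", "si_fixation", "mixotrophy", "coloniality"):
        invalid = df.index[~df[col].isin(["Y", "N"])]
        if len(invalid):
            raise ValueError(f"{path}: {col} must be Y or N (genus {invalid[0]!r})")
    return df


def read_zoop(path) -> pd.DataFrame:
    """Cladoceran biomass per event, indexed by (basin, datetime)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"basin": str, "datetime": str})
    _require_columns(df, ("basin", "datetime", "biomass_ug_l"), path)
    neg = df.index[(df["biomass_ug_l"].isna()) | (df["biomass_ug_l"] < 0)]
    if len(neg):
        raise ValueError(f"{path}: invalid biomass on line {_line(neg[0])}")
    return df.set_index(["basin", "datetime"])[["biomass_ug_l"]].astype(float)


def check_genera(biomass: pd.DataFrame, traits: pd.DataFrame) -> None:
    """Every genus in the biomass matrix must appear in the trait matrix."""
    unknown = [g for g in biomass.columns if g not in traits.index]
    if unknown:
        raise ValueError(f"genera missing from the trait matrix: {unknown}")


# --- writers ----------------------------------------------------------------


def write_profiles(profiles: Dict[EventKey, DepthProfile], path) -> None:
    rows = []
    for (basin, dt), prof in profiles.items():
        for z, t in zip(prof.depths, prof.values):
            rows.append({"basin": basin, "datetime": dt, "depth_m": z, "temp_c": t})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_spectral(spectra: Dict[EventKey, SpectralProfileSet], path) -> None:
    rows = []
    for (basin, dt), pset in spectra.items():
        for i, z in enumerate(pset.depths):
            row = {"basin": basin, "datetime": dt, "depth_m": z}
            for g in SPECTRAL_GROUPS:
                row[f"chl_{g}"] = pset.concentrations[g][i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_biomass(biomass: pd.DataFrame, path) -> None:
    out = biomass.copy()
    out.index.names = ["basin", "datetime"]
    out.reset_index().to_csv(path, index=False)


def write_traits(traits: pd.DataFrame, path) -> None:
    out = traits.copy()
    out.index.name = "genus"
    out.reset_index().to_csv(path, index=False)


def write_zoop(zoop: pd.DataFrame, path) -> None:
    out = zoop.copy()
    if not isinstance(out.index, pd.MultiIndex):
        out = out.set_index(["basin", "datetime"])
    out.index.names = ["basin", "datetime"]
    out.reset_index().to_csv(path, index=False)


# --- configuration ----------------------------------------------------------

DEFAULT_CONFIG = {
    # simulation
    "seed": 0,
    "n_basins": 3,
    "n_dates": 8,
    "thermo_depth_true": [4.0, 6.0, 8.0],
    "meta_width_true": [1.5, 2.0, 2.5],
    "noise_sd_temp": 0.1,
    "noise_sd_chla": 0.05,
    # hydrophysics
    "metalimnion_threshold": 0.1,
    "min_gradient": 0.05,
    # overlap
    "n_grid": 512,
    "detection_floor": 0.05,
    "absent_as_zero": False,
    # inference
    "n_boot": 10000,
    "n_perm": 10000,
    # io
    "outdir": "results",
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML key/value config, falling back to documented defaults.

    Unknown keys raise, so typos fail fast.
    """
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a key: value mapping")
        unknown = [k for k in user if k not in DEFAULT_CONFIG and not k.endswith("_path")]
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        config.update(user)
    if overrides:
        config.update({k: v for k, v in overrides.items() if v is not None})
    return config
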