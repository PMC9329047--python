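"""Delimited-text readers/writers and run configuration.

All interchange is comma-separated UTF-8 with a header row and "." decimals.
Column schemas:

* profiles: ``core_id,campaign,species,depth_m,conc_uM``
* incubation: ``core_id,species,time_d,conc_uM,v_olw_L,v_repl_L,conc_repl_uM``
* solids: ``core_id,campaign,species,extraction,depth_top_m,depth_bot_m,conc_umol_g``

Readers apply unit conversion at the boundary, sort out-of-order depth rows
with a warning, and raise :class:`SchemaError` naming any missing column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, SchemaError
from .incubation import DEFAULT_CORE_AREA, IncubationEvent, IncubationSeries
from .inventory import SolidPhaseProfile
from .physchem import DEFAULT_AS_SPECIES
from .profile_flux import DepthProfile

logger = logging.getLogger("benthicflux")

PROFILE_COLUMNS = ["core_id", "campaign", "species", "depth_m", "conc_uM"]
INCUBATION_COLUMNS = [
    "core_id",
    "species",
    "time_d",
    "conc_uM",
    "v_olw_L",
    "v_repl_L",
    "conc_repl_uM",
]
SOLIDS_COLUMNS = [
    "core_id",
    "campaign",
    "species",
    "extraction",
    "depth_top_m",
    "depth_bot_m",
    "conc_umol_g",
]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )
    logger.info("read %d rows from %s", len(df), path)
    return df


def read_profiles(path) -> list[DepthProfile]:
    """Read depth profiles, one :class:`DepthProfile` per (core, campaign, species)."""
    df = _read_table(path, PROFILE_COLUMNS)
    profiles = []
    for (core_id, campaign, species), grp in df.groupby(
        ["core_id", "campaign", "species"], sort=True
    ):
        depths = grp["depth_m"].to_numpy(dtype=float)
        if not np.all(np.diff(depths) > 0):
            logger.warning(
                "profile %s/%s/%s: depths out of order; sorting on load",
                core_id,
                campaign,
                species,
            )
            grp = grp.sort_values("depth_m")
            depths = grp["depth_m"].to_numpy(dtype=float)
        profiles.append(
            DepthProfile(
                species=str(species),
                depths=depths,
                concentrations=grp["conc_uM"].to_numpy(dtype=float),
                core_id=str(core_id),
                campaign=str(campaign),
            )
        )
    return profiles


def write_profiles(profiles: list[DepthProfile], path) -> None:
    rows = []
    for p in profiles:
        for d, c in zip(p.depths, p.concentrations):
            rows.append(
                dict(
                    core_id=p.core_id,
                    campaign=p.campaign,
                    species=p.species,
                    depth_m=d,
                    conc_uM=c,
                )
            )
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def read_incubation(
    path, core_area: float = DEFAULT_CORE_AREA
) -> list[IncubationSeries]:
    """Read incubation series, one per (core, species); core area from config."""
    df = _read_table(path, INCUBATION_COLUMNS)
    series = []
    for (core_id, species), grp in df.groupby(["core_id", "species"], sort=True):
        grp = grp.sort_values("time_d")
        events = [
            IncubationEvent(
                time=float(r.time_d),
                conc_end=float(r.conc_uM),
                v_olw=float(r.v_olw_L),
                v_repl=float(r.v_repl_L),
                conc_repl=float(r.conc_repl_uM),
            )
            for r in grp.itertuples()
        ]
        series.append(
            IncubationSeries(
                core_id=str(core_id),
                species=str(species),
                events=events,
                core_area=core_area,
            )
        )
    return series


def write_incubation(series: list[IncubationSeries], path) -> None:
    rows = []
    for s in series:
        for e in s.events:
            rows.append(
                dict(
                    core_id=s.core_id,
                    species=s.species,
                    time_d=e.time,
                    conc_uM=e.conc_end,
                    v_olw_L=e.v_olw,
                    v_repl_L=e.v_repl,
                    conc_repl_uM=e.conc_repl,
                )
            )
    pd.DataFrame(rows, columns=INCUBATION_COLUMNS).to_csv(path, index=False)


def read_solids(path) -> list[SolidPhaseProfile]:
    """Read solid-phase profiles, one per (core, campaign, species, extraction)."""
    df = _read_table(path, SOLIDS_COLUMNS)
    profiles = []
    keys = ["core_id", "campaign", "species", "extraction"]
    for (core_id, campaign, species, extraction), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("depth_top_m")
        profiles.append(
            SolidPhaseProfile(
                species=str(species),
                depth_tops=grp["depth_top_m"].to_numpy(dtype=float),
                depth_bots=grp["depth_bot_m"].to_numpy(dtype=float),
                concentrations=grp["conc_umol_g"].to_numpy(dtype=float),
                extraction=str(extraction),
                core_id=str(core_id),
                campaign=str(campaign),
            )
        )
    return profiles


def write_solids(profiles: list[SolidPhaseProfile], path) -> None:
    rows = []
    for p in profiles:
        for top, bot, c in zip(p.depth_tops, p.depth_bots, p.concentrations):
            rows.append(
                dict(
                    core_id=p.core_id,
                    campaign=p.campaign,
                    species=p.species,
                    extraction=p.extraction,
                    depth_top_m=top,
                    depth_bot_m=bot,
                    conc_umol_g=c,
                )
            )
    pd.DataFrame(rows, columns=SOLIDS_COLUMNS).to_csv(path, index=False)


def write_truth(truth, path) -> None:
    """Write a generator truth record as a key,value delimited table."""
    rows = [("name", truth.name)]
    for s, v in truth.production_rates.items():
        rows.append((f"production_rate_mmol_m2_d.{s}", v))
    for s, v in truth.upward_fractions.items():
        rows.append((f"upward_fraction.{s}", v))
    for k, v in truth.features.items():
        rows.append((f"feature.{k}", "" if v is None else v))
    for s, v in truth.released_umol.items():
        rows.append((f"released_umol.{s}", v))
    for s, v in truth.cumulative_mmol_m2.items():
        rows.append((f"cumulative_mmol_m2.{s}", v))
    for s, v in truth.inventory_change_mmol_m2.items():
        rows.append((f"inventory_change_mmol_m2.{s}", v))
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(path, index=False)


def write_scenario(scenario, outdir) -> None:
    """Write a generated scenario to a directory in the interchange formats.

    Produces ``profiles.csv``, ``incubation.csv``, ``solids_before.csv``,
    ``solids_after.csv`` and ``truth.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_profiles(list(scenario.profiles.values()), outdir / "profiles.csv")
    write_incubation(list(scenario.incubations.values()), outdir / "incubation.csv")
    write_solids(list(scenario.solids_before.values()), outdir / "solids_before.csv")
    write_solids(list(scenario.solids_after.values()), outdir / "solids_after.csv")
    write_truth(scenario.truth, outdir / "truth.csv")


@dataclass
class AnalysisConfig:
    """Validated run configuration; every defaulted value is echoed to the log."""

    input_dir: str = "."
    output_dir: str = "results"
    profiles_file: str = "profiles.csv"
    incubation_file: str = "incubation.csv"
    solids_before_file: str = "solids_before.csv"
    solids_after_file: str = "solids_after.csv"
    porosity: float = 0.85
    solid_density: float = 2.6
    salinity: float = 30.0
    temperature: float = 4.0
    detection_limit_uM: float = 1.0
    gradient_window_points: int = 4
    as_species: str = DEFAULT_AS_SPECIES
    core_area_m2: float = DEFAULT_CORE_AREA
    mixed_layer_height_m: float = 15.0
    inventory_top_m: float = 0.0
    inventory_bottom_m: float = 0.01
    registry_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gradient_window_points < 2:
            raise DataError("gradient_window_points must be >= 2")
        if self.detection_limit_uM <= 0:
            raise DataError("detection_limit_uM must be > 0")
        if self.core_area_m2 <= 0:
            raise DataError("core_area_m2 must be > 0")
        if not self.inventory_top_m < self.inventory_bottom_m:
            raise DataError("inventory interval must have top < bottom")


def load_config(path) -> AnalysisConfig:
    """Load a YAML key-value config; unknown keys raise, defaults are logged."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    cfg = AnalysisConfig(**raw)
    for f in fields(AnalysisConfig):
        if f.name not in raw:
            logger.info("config: %s defaulted to %r", f.name, getattr(cfg, f.name))
    return cfg
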