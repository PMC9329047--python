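"""End-to-end analysis pipeline: features -> fluxes -> inventories -> budgets."""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

import pandas as pd

from . import budget, incubation, inventory, profile_flux
from .errors import BenthicfluxError, NoInteriorPeakError, PipelineError
from .io import (
    AnalysisConfig,
    read_incubation,
    read_profiles,
    read_solids,
)
from .physchem import DiffusivityRegistry, SedimentProperties

logger = logging.getLogger("benthicflux")

MICROSENSOR = {"O2", "H2S", "pH"}


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


@_stage("features")
def _features_stage(profiles, config) -> list[dict]:
    by_core = defaultdict(dict)
    for p in profiles:
        if p.species in MICROSENSOR:
            by_core[(p.core_id, p.campaign)][p.species] = p
    rows = []
    for (core_id, campaign), group in sorted(by_core.items()):
        if not MICROSENSOR <= set(group):
            logger.info(
                "features: core %s/%s lacks a full O2/H2S/pH set; skipped",
                core_id,
                campaign,
            )
            continue
        feats = profile_flux.extract_features(
            group["O2"], group["H2S"], group["pH"], config.detection_limit_uM
        )
        for metric, value in (
            ("opd_m", feats.opd),
            ("sad_m", feats.sad),
            ("suboxic_thickness_m", feats.suboxic_thickness),
            ("ph_max", feats.ph_max_value),
            ("ph_min", feats.ph_min_value),
        ):
            rows.append(
                dict(
                    section="features",
                    core_id=core_id,
                    campaign=campaign,
                    species="",
                    metric=metric,
                    value=value,
                )
            )
    return rows


@_stage("profile-flux")
def _profile_flux_stage(profiles, props, config, registry) -> list[dict]:
    rows = []
    for p in profiles:
        if p.species in MICROSENSOR:
            continue
        n = min(config.gradient_window_points, len(p))
        swi_window = (p.depths[0], float(p.depths[n - 1]) + 1e-12)
        flux = profile_flux.diffusive_flux(
            p, props, swi_window, registry, config.as_species
        )
        rows.append(
            dict(
                section="profile_flux",
                core_id=p.core_id,
                campaign=p.campaign,
                species=p.species,
                metric="swi_flux_mmol_m2_d",
                value=flux.flux,
            )
        )
        try:
            part = profile_flux.peak_partition(
                p, props, config.gradient_window_points, registry, config.as_species
            )
        except NoInteriorPeakError:
            logger.info(
                "profile-flux: %s/%s/%s has no interior peak",
                p.core_id,
                p.campaign,
                p.species,
            )
            continue
        for metric, value in (
            ("production_mmol_m2_d", part.production),
            ("upward_fraction", part.upward_fraction),
            ("peak_depth_m", part.peak_depth),
        ):
            rows.append(
                dict(
                    section="profile_flux",
                    core_id=p.core_id,
                    campaign=p.campaign,
                    species=p.species,
                    metric=metric,
                    value=value,
                )
            )
    return rows


@_stage("incubation")
def _incubation_stage(series_list, config) -> tuple[list[dict], dict]:
    rows = []
    cumulative_by_species = defaultdict(list)
    for s in series_list:
        fs = incubation.interval_fluxes(s)
        cum = fs.cumulative
        cumulative_by_species[s.species].append(cum)
        onset = incubation.detect_onset(s, config.detection_limit_uM)
        rows.append(
            dict(
                section="incubation",
                core_id=s.core_id,
                campaign="",
                species=s.species,
                metric="cumulative_mmol_m2",
                value=cum,
            )
        )
        if onset is not None:
            rows.append(
                dict(
                    section="incubation",
                    core_id=s.core_id,
                    campaign="",
                    species=s.species,
                    metric="onset_d",
                    value=onset,
                )
            )
        n_neg = sum(iv.negative for iv in fs.intervals)
        if n_neg:
            rows.append(
                dict(
                    section="incubation",
                    core_id=s.core_id,
                    campaign="",
                    species=s.species,
                    metric="qc_negative_intervals",
                    value=n_neg,
                )
            )
    for species, values in sorted(cumulative_by_species.items()):
        stats = incubation.replicate_stats(values)
        rows.append(
            dict(
                section="incubation",
                core_id="all",
                campaign="",
                species=species,
                metric="cumulative_mean_mmol_m2",
                value=stats.mean,
            )
        )
        if stats.sd is not None:
            rows.append(
                dict(
                    section="incubation",
                    core_id="all",
                    campaign="",
                    species=species,
                    metric="cumulative_sd_mmol_m2",
                    value=stats.sd,
                )
            )
    return rows, dict(cumulative_by_species)


@_stage("inventory")
def _inventory_stage(before, after, props, config) -> list[dict]:
    rows = []
    after_by_key = {(p.species, p.extraction, p.campaign): p for p in after}
    for b in before:
        key = (b.species, b.extraction, b.campaign)
        if key not in after_by_key:
            logger.info("inventory: no matching after-profile for %s", key)
            continue
        change = inventory.inventory_change(
            b, after_by_key[key], props, config.inventory_top_m, config.inventory_bottom_m
        )
        rows.append(
            dict(
                section="inventory",
                core_id="",
                campaign=b.campaign,
                species=b.species,
                metric="inventory_change_mmol_m2",
                value=change,
            )
        )
    return rows


@_stage("budget")
def _budget_stage(cumulative_by_species, config) -> list[dict]:
    rows = []
    as_fluxes = cumulative_by_species.get("dAs", [])
    fe_fluxes = cumulative_by_species.get("dFe", [])
    if as_fluxes:
        try:
            lo, hi = budget.dilution_range(as_fluxes, config.mixed_layer_height_m)
            rows.append(
                dict(
                    section="budget",
                    core_id="",
                    campaign="",
                    species="dAs",
                    metric="dilution_min_nM",
                    value=lo,
                )
            )
            rows.append(
                dict(
                    section="budget",
                    core_id="",
                    campaign="",
                    species="dAs",
                    metric="dilution_max_nM",
                    value=hi,
                )
            )
        except BenthicfluxError as exc:
            logger.info("budget: dilution range skipped (%s)", exc)
    if as_fluxes and fe_fluxes and len(as_fluxes) == len(fe_fluxes):
        ratio = budget.element_ratio(as_fluxes, fe_fluxes)
        rows.append(
            dict(
                section="budget",
                core_id="",
                campaign="",
                species="dAs/dFe",
                metric=f"element_ratio[{ratio.method}]",
                value=ratio.ratio,
            )
        )
    return rows


def run_pipeline(config: AnalysisConfig) -> pd.DataFrame:
    """Run all stages on the configured input directory.

    Writes ``results.csv`` (machine-readable) and ``report.txt`` (human
    readable) to the output directory and returns the results table.  Any
    stage failure raises :class:`PipelineError` with a stage-labelled message.
    """
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    props = SedimentProperties(
        porosity=config.porosity,
        solid_density=config.solid_density,
        salinity=config.salinity,
        temperature=config.temperature,
    )
    registry = (
        DiffusivityRegistry.from_csv(config.registry_path)
        if config.registry_path
        else DiffusivityRegistry.default()
    )

    rows: list[dict] = []
    profiles_path = indir / config.profiles_file
    if profiles_path.exists():
        profiles = read_profiles(profiles_path)
        rows += _features_stage(profiles, config)
        rows += _profile_flux_stage(profiles, props, config, registry)
    cumulative_by_species: dict = {}
    incubation_path = indir / config.incubation_file
    if incubation_path.exists():
        series_list = read_incubation(incubation_path, config.core_area_m2)
        inc_rows, cumulative_by_species = _incubation_stage(series_list, config)
        rows += inc_rows
    before_path = indir / config.solids_before_file
    after_path = indir / config.solids_after_file
    if before_path.exists() and after_path.exists():
        rows += _inventory_stage(
            read_solids(before_path), read_solids(after_path), props, config
        )
    if cumulative_by_species:
        rows += _budget_stage(cumulative_by_species, config)
    if not rows:
        raise PipelineError(
            f"[input] no usable inputs found under {indir} "
            f"(looked for {config.profiles_file}, {config.incubation_file}, "
            f"{config.solids_before_file}/{config.solids_after_file})"
        )

    results = pd.DataFrame(
        rows, columns=["section", "core_id", "campaign", "species", "metric", "value"]
    )
    results.to_csv(outdir / "results.csv", index=False)
    with open(outdir / "report.txt", "w", encoding="utf-8") as fh:
        fh.write("benthicflux analysis report\n")
        fh.write(f"inputs: {indir.resolve()}\n")
        fh.write(
            f"sediment: porosity={props.porosity}, rho_s={props.solid_density} "
            f"g cm-3, S={props.salinity}, T={props.temperature} degC\n"
        )
        fh.write(
            f"assumed As species: {config.as_species}; depth positive downward, "
            "SWI at 0; fluxes positive downward; windows [top, bottom)\n\n"
        )
        for section, grp in results.groupby("section", sort=True):
            fh.write(f"== {section} ==\n")
            for r in grp.itertuples():
                label = "/".join(x for x in (r.core_id, r.campaign, r.species) if x)
                fh.write(f"  {label:30s} {r.metric:32s} {r.value:.6g}\n")
            fh.write("\n")
    logger.info("wrote %s and report.txt to %s", "results.csv", outdir)
    return results
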