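"""Synthetic scenario generator with exactly known truth.

Everything the analysis pipeline consumes can be generated here: steady-state
pore-water profiles (piecewise linear, so true diffusive fluxes are analytic),
microsensor O2/H2S/pH profiles with prescribed penetration/appearance depths
and pH extrema, solid-phase profiles with prescribed inventory changes, and
closed-core incubation time series driven by analytic flux histories with an
exact released-mass ledger.

Three presets emulate the seasonal regimes of a seasonally hypoxic basin:

* ``march`` — electrogenic sulfur oxidation: deep suboxic zone, alkaline
  subsurface pH maximum, deep acidic minimum, strong subsurface dFe peak,
  delayed sulfide efflux in the incubation.
* ``may`` — bioturbation-driven iron cycling: shallow oxic zone, acidic pH
  minimum at the interface, shallower dFe peak, shorter sulfide delay,
  immediate As release.
* ``august`` — euxinic: sulfide from the interface, no suboxic zone, no
  detectable Fe/As efflux, immediate sulfide efflux.

All randomness flows through one seeded ``numpy.random.Generator``; identical
(parameters, seed) give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, RangeError
from .incubation import DEFAULT_CORE_AREA, IncubationEvent, IncubationSeries
from .inventory import SolidPhaseProfile
from .physchem import (
    DEFAULT_AS_SPECIES,
    DiffusivityRegistry,
    SedimentProperties,
)
from .profile_flux import DepthProfile

# ---------------------------------------------------------------------------
# analytic flux histories (all rates mmol m-2 d-1, time in d)


@dataclass(frozen=True)
class ConstantFlux:
    rate: float

    def __call__(self, t):
        return self.rate * np.ones_like(np.asarray(t, dtype=float))

    def integral(self, t0: float, t1: float) -> float:
        return self.rate * (t1 - t0)


@dataclass(frozen=True)
class ExponentialPulse:
    """Immediate release decaying as ``peak * exp(-t / timescale)``."""

    peak: float
    timescale: float

    def __call__(self, t):
        return self.peak * np.exp(-np.asarray(t, dtype=float) / self.timescale)

    def integral(self, t0: float, t1: float) -> float:
        tau = self.timescale
        return self.peak * tau * (math.exp(-t0 / tau) - math.exp(-t1 / tau))


@dataclass(frozen=True)
class LogisticOnset:
    """Delayed onset rising to a plateau around ``onset_time``."""

    plateau: float
    onset_time: float
    steepness: float  # d; smaller = sharper onset

    def __call__(self, t):
        x = (np.asarray(t, dtype=float) - self.onset_time) / self.steepness
        return self.plateau / (1.0 + np.exp(-x))

    def _antiderivative(self, t: float) -> float:
        x = (t - self.onset_time) / self.steepness
        return self.plateau * self.steepness * float(np.logaddexp(0.0, x))

    def integral(self, t0: float, t1: float) -> float:
        return self._antiderivative(t1) - self._antiderivative(t0)


@dataclass(frozen=True)
class DelayedPulse:
    """Release peaking at ``peak_time``: ``peak * (t/tp) * exp(1 - t/tp)``."""

    peak: float
    peak_time: float

    def __call__(self, t):
        x = np.asarray(t, dtype=float) / self.peak_time
        return self.peak * x * np.exp(1.0 - x)

    def integral(self, t0: float, t1: float) -> float:
        tp = self.peak_time

        def anti(t: float) -> float:
            return -self.peak * math.e * (t + tp) * math.exp(-t / tp)

        return anti(t1) - anti(t0)


@dataclass(frozen=True)
class SaturatingFlux:
    """Immediate release approaching a plateau: ``p * (1 - exp(-t/tau))``."""

    plateau: float
    timescale: float

    def __call__(self, t):
        return self.plateau * (
            1.0 - np.exp(-np.asarray(t, dtype=float) / self.timescale)
        )

    def integral(self, t0: float, t1: float) -> float:
        tau = self.timescale

        def anti(t: float) -> float:
            return self.plateau * (t + tau * math.exp(-t / tau))

        return anti(t1) - anti(t0)


# ---------------------------------------------------------------------------
# truth records


@dataclass(frozen=True)
class SteadyProfileTruth:
    """Analytic truth behind one generated steady-state profile."""

    production_rate: float  # mmol m-2 d-1
    upward_fraction: float
    peak_depth: float  # m
    peak_concentration: float  # mmol m-3
    zero_depth: float  # m, where the downward limb reaches zero
    d0: float
    phi_ds: float  # porosity * D0 / theta2


@dataclass
class ScenarioTruth:
    """Generator-side record of everything the estimators should recover."""

    name: str
    production_rates: dict[str, float] = field(default_factory=dict)
    upward_fractions: dict[str, float] = field(default_factory=dict)
    features: dict[str, float | None] = field(default_factory=dict)
    incubation_flux: dict[str, object] = field(default_factory=dict)
    schedule: np.ndarray | None = None
    released_umol: dict[str, float] = field(default_factory=dict)
    cumulative_mmol_m2: dict[str, float] = field(default_factory=dict)
    inventory_change_mmol_m2: dict[str, float] = field(default_factory=dict)
    profile_truths: dict[str, SteadyProfileTruth] = field(default_factory=dict)


@dataclass
class Scenario:
    """Full generated dataset for one seasonal regime."""

    name: str
    props: SedimentProperties
    profiles: dict[str, DepthProfile]
    solids_before: dict[str, SolidPhaseProfile]
    solids_after: dict[str, SolidPhaseProfile]
    incubations: dict[str, IncubationSeries]
    truth: ScenarioTruth


# ---------------------------------------------------------------------------
# steady-state pore-water profile


def make_steady_profile(
    species: str,
    production_rate: float,
    upward_fraction: float,
    production_depth: float,
    props: SedimentProperties,
    grid_spacing: float = 0.5e-3,
    extent: float = 60e-3,
    consumption_depth: float | None = None,
    noise_cv: float = 0.0,
    seed: int | None = None,
    registry: DiffusivityRegistry | None = None,
    as_species: str = DEFAULT_AS_SPECIES,
    **profile_kwargs,
) -> tuple[DepthProfile, SteadyProfileTruth]:
    """Piecewise-linear steady-state profile with analytically known fluxes.

    A solute is produced at the plane ``production_depth`` at the stated
    rate; a fraction diffuses up to a zero-concentration interface and the
    rest down to a zero-concentration sink.  Both limb slopes follow from
    ``porosity * D0 / theta2``, so flux estimators recover the truth exactly
    on a noiseless grid.  Multiplicative Gaussian noise with coefficient of
    variation ``noise_cv`` is applied when requested (seeded).
    """
    if production_rate < 0.0:
        raise RangeError("production_rate must be >= 0")
    if not 0.0 <= upward_fraction <= 1.0:
        raise RangeError("upward_fraction must be in [0, 1]")
    if grid_spacing <= 0.0 or extent <= 0.0:
        raise RangeError("grid_spacing and extent must be > 0")
    if not 0.0 < production_depth < extent:
        raise DataError(
            f"production_depth {production_depth} m must lie inside (0, {extent}) m"
        )
    reg = registry if registry is not None else DiffusivityRegistry.default()
    d0 = reg.d0(species, props.temperature, props.salinity, as_species)
    phi_ds = props.porosity * d0 / props.tortuosity_squared

    xp = production_depth
    if production_rate == 0.0:
        peak_conc = 0.0
        zero_depth = xp
    else:
        slope_up = upward_fraction * production_rate / phi_ds
        peak_conc = slope_up * xp
        if upward_fraction >= 1.0:
            zero_depth = extent  # no downward limb; flat below the peak
        elif upward_fraction == 0.0:
            raise DataError(
                "upward_fraction = 0 gives a surface-pinned profile with no "
                "interior peak; not supported"
            )
        else:
            slope_down = (1.0 - upward_fraction) * production_rate / phi_ds
            zero_depth = xp + peak_conc / slope_down
    if consumption_depth is not None:
        if consumption_depth > extent:
            raise DataError("consumption_depth must lie within the grid extent")
        if zero_depth > consumption_depth + 1e-12:
            raise DataError(
                f"infeasible geometry: downward limb reaches zero at "
                f"{zero_depth:.4g} m, below consumption_depth {consumption_depth} m"
            )

    depths = np.arange(0.0, extent + grid_spacing / 2.0, grid_spacing)
    if production_rate == 0.0:
        conc = np.zeros_like(depths)
    elif upward_fraction >= 1.0:
        conc = np.interp(depths, [0.0, xp, extent], [0.0, peak_conc, peak_conc])
    else:
        conc = np.interp(
            depths,
            [0.0, xp, min(zero_depth, extent), extent],
            [0.0, peak_conc, 0.0, 0.0],
        )
    if noise_cv > 0.0:
        rng = np.random.default_rng(seed)
        conc = conc * (1.0 + noise_cv * rng.standard_normal(conc.shape))
        conc = np.maximum(conc, 0.0)
    profile = DepthProfile(
        species=species, depths=depths, concentrations=conc, **profile_kwargs
    )
    truth = SteadyProfileTruth(
        production_rate=production_rate,
        upward_fraction=upward_fraction,
        peak_depth=xp,
        peak_concentration=peak_conc,
        zero_depth=zero_depth,
        d0=d0,
        phi_ds=phi_ds,
    )
    return profile, truth


def make_attenuation_profile(
    species: str,
    surface_conc: float,
    attenuation_length: float,
    props: SedimentProperties,
    grid_spacing: float = 0.5e-3,
    extent: float = 60e-3,
    noise_cv: float = 0.0,
    seed: int | None = None,
    registry: DiffusivityRegistry | None = None,
    as_species: str = DEFAULT_AS_SPECIES,
    **profile_kwargs,
) -> tuple[DepthProfile, float]:
    """Smooth exponential profile with an analytic interface flux.

    Steady state of diffusion with first-order consumption gives
    ``C(x) = C0 * exp(-x / L)``; the downward flux across the interface is
    ``phi * Ds * C0 / L`` (positive, into the sediment).  Returns the profile
    and that true flux.  Useful for convergence tests: a finite fit window
    sees the curvature, so the estimation error shrinks with the grid.
    """
    if surface_conc < 0.0 or attenuation_length <= 0.0:
        raise RangeError("surface_conc >= 0 and attenuation_length > 0 required")
    reg = registry if registry is not None else DiffusivityRegistry.default()
    d0 = reg.d0(species, props.temperature, props.salinity, as_species)
    phi_ds = props.porosity * d0 / props.tortuosity_squared
    depths = np.arange(0.0, extent + grid_spacing / 2.0, grid_spacing)
    conc = surface_conc * np.exp(-depths / attenuation_length)
    if noise_cv > 0.0:
        rng = np.random.default_rng(seed)
        conc = np.maximum(conc * (1.0 + noise_cv * rng.standard_normal(conc.shape)), 0.0)
    profile = DepthProfile(
        species=species, depths=depths, concentrations=conc, **profile_kwargs
    )
    true_flux = phi_ds * surface_conc / attenuation_length
    return profile, true_flux


# ---------------------------------------------------------------------------
# microsensor profile templates


def _interp_profile(
    species: str, control: list[tuple[float, float]], grid_spacing: float, **kwargs
) -> DepthProfile:
    xs = [p[0] for p in control]
    cs = [p[1] for p in control]
    depths = np.arange(xs[0], xs[-1] + grid_spacing / 2.0, grid_spacing)
    return DepthProfile(
        species=species,
        depths=depths,
        concentrations=np.interp(depths, xs, cs),
        **kwargs,
    )


def make_o2_profile(
    bottom_water: float,
    opd: float | None,
    detection_limit: float = 1.0,
    grid_spacing: float = 0.1e-3,
    extent: float = 5e-3,
    **kwargs,
) -> DepthProfile:
    """O2 microsensor profile crossing the detection limit exactly at ``opd``.

    ``opd = None`` produces an anoxic profile (O2 identically zero).
    """
    if opd is None:
        control = [(-2e-3, 0.0), (extent, 0.0)]
    else:
        below = min(opd + 5 * grid_spacing, extent)
        control = [
            (-2e-3, bottom_water),
            (0.0, bottom_water),
            (opd, detection_limit),
            (below, 0.0),
            (extent, 0.0),
        ]
    return _interp_profile("O2", control, grid_spacing, **kwargs)


def make_h2s_profile(
    sad: float | None,
    slope: float = 1000.0,  # mmol m-3 per m (1 uM per mm)
    detection_limit: float = 1.0,
    grid_spacing: float = 0.5e-3,
    extent: float = 60e-3,
    **kwargs,
) -> DepthProfile:
    """Sulfide profile crossing the detection limit exactly at ``sad``.

    ``sad = None`` gives an all-zero profile (sulfide never appears);
    ``sad = 0`` gives sulfide from the interface upward-extrapolated into a
    thin overlying-water segment.
    """
    start = -2e-3
    if sad is None:
        control = [(start, 0.0), (extent, 0.0)]
    else:
        x0 = sad - detection_limit / slope  # where the linear rise leaves zero
        if x0 <= start:
            raise DataError("sulfide ramp starts above the profile")
        control = [(start, 0.0), (x0, 0.0), (extent, (extent - x0) * slope)]
    return _interp_profile("H2S", control, grid_spacing, **kwargs)


def make_ph_profile(
    control: list[tuple[float, float]],
    grid_spacing: float = 0.5e-3,
    **kwargs,
) -> DepthProfile:
    """pH profile through the given (depth, pH) control points."""
    return _interp_profile("pH", control, grid_spacing, **kwargs)


# ---------------------------------------------------------------------------
# incubation simulator


def simulate_incubation(
    flux_histories: dict[str, object],
    schedule,
    replacement_fraction: float = 0.75,
    v_olw: float = 0.42,
    core_area: float = DEFAULT_CORE_AREA,
    conc_repl: float = 0.0,
    initial_conc: dict[str, float] | float = 0.0,
    noise_cv: float = 0.0,
    seed: int | None = None,
    core_id: str = "sim",
) -> tuple[dict[str, IncubationSeries], dict[str, float]]:
    """Forward mass balance of a closed-core incubation with replacement.

    Between samplings the overlying inventory grows by the exact analytic
    time-integral of the true flux times the core area; at each sampling the
    (optionally noisy) concentration is recorded and the replacement applied.
    Returns the per-species series and a ledger of total released µmol.
    """
    times = np.asarray(schedule, dtype=float)
    if len(times) < 2 or not np.all(np.diff(times) > 0):
        raise DataError("schedule must contain >= 2 strictly increasing times")
    if not 0.0 <= replacement_fraction <= 1.0:
        raise RangeError("replacement_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    v_repl = replacement_fraction * v_olw
    series: dict[str, IncubationSeries] = {}
    ledger: dict[str, float] = {}
    for species in sorted(flux_histories):
        fh = flux_histories[species]
        c0 = (
            initial_conc.get(species, 0.0)
            if isinstance(initial_conc, dict)
            else initial_conc
        )
        events = [
            IncubationEvent(
                time=float(times[0]),
                conc_end=c0,
                v_olw=v_olw,
                v_repl=v_repl,
                conc_repl=conc_repl,
            )
        ]
        inv = v_repl * conc_repl + (v_olw - v_repl) * c0  # umol, post-replacement
        total = 0.0
        for t_prev, t in zip(times[:-1], times[1:]):
            released = core_area * fh.integral(float(t_prev), float(t)) * 1000.0
            inv += released
            total += released
            conc_true = inv / v_olw
            measured = conc_true
            if noise_cv > 0.0:
                measured = max(
                    conc_true * (1.0 + noise_cv * float(rng.standard_normal())), 0.0
                )
            events.append(
                IncubationEvent(
                    time=float(t),
                    conc_end=measured,
                    v_olw=v_olw,
                    v_repl=v_repl,
                    conc_repl=conc_repl,
                )
            )
            inv = v_repl * conc_repl + (v_olw - v_repl) * conc_true
        series[species] = IncubationSeries(
            core_id=core_id, species=species, events=events, core_area=core_area
        )
        ledger[species] = total
    return series, ledger


# ---------------------------------------------------------------------------
# seasonal presets

MM = 1e-3  # mm expressed in m

PRESETS: dict[str, dict] = {
    "march": {
        "props": dict(porosity=0.85, solid_density=2.6, salinity=30.0, temperature=4.0),
        "o2": dict(bottom_water=329.0, opd=1.4 * MM),
        "sad": 41.0 * MM,
        "ph_control": [
            (-2 * MM, 8.10),
            (0.0, 8.30),
            (1.5 * MM, 8.82),  # alkaline maximum near the oxic zone
            (20 * MM, 7.20),
            (41 * MM, 6.40),  # acidic minimum near the sulfide horizon
            (60 * MM, 6.60),
        ],
        "dFe": dict(rate=2.3, upward_fraction=0.60, production_depth=15 * MM),
        "dAs": dict(rate=0.85e-3, upward_fraction=0.45, production_depth=20 * MM),
        "incubation": {
            "dFe": ExponentialPulse(peak=4.0, timescale=30.0),
            "H2S": LogisticOnset(plateau=6.0, onset_time=75.0, steepness=4.0),
            "dAs": DelayedPulse(peak=3.0e-3, peak_time=50.0),
        },
        "schedule_weeks": 23,
        "solids_loss": {"dAs": 0.841, "dFe": 491.0},
    },
    "may": {
        "props": dict(porosity=0.85, solid_density=2.6, salinity=30.0, temperature=4.0),
        "o2": dict(bottom_water=175.0, opd=1.0 * MM),
        "sad": 38.0 * MM,  # OPD + ~37 mm suboxic zone
        "ph_control": [
            (0.0, 7.40),
            (1.0 * MM, 7.10),  # acidic minimum in the oxic zone
            (10 * MM, 7.70),  # recovery below
            (60 * MM, 7.60),
        ],
        "dFe": dict(rate=1.4, upward_fraction=0.78, production_depth=5 * MM),
        "dAs": dict(rate=1.52e-3, upward_fraction=0.60, production_depth=2.5 * MM),
        "incubation": {
            "dFe": ExponentialPulse(peak=2.5, timescale=25.0),
            "H2S": LogisticOnset(plateau=4.0, onset_time=45.0, steepness=3.0),
            "dAs": ExponentialPulse(peak=17.0e-3, timescale=25.0),
        },
        "schedule_weeks": 15,
        "solids_loss": {"dAs": 0.436, "dFe": 14.1},
    },
    "august": {
        "props": dict(porosity=0.85, solid_density=2.6, salinity=30.0, temperature=4.0),
        "o2": dict(bottom_water=0.0, opd=None),  # anoxic bottom water
        "sad": 0.0,  # sulfide from the interface
        "ph_control": [
            (0.0, 7.60),
            (5 * MM, 7.30),  # minimum in the first 0.5 cm, constant below
            (60 * MM, 7.30),
        ],
        "dFe": dict(rate=0.0, upward_fraction=0.5, production_depth=15 * MM),
        # rate tuned at runtime to a ~1.5 uM dAs peak at 2.5 cm depth
        "dAs": dict(peak_conc=1.5, upward_fraction=0.50, production_depth=25 * MM),
        "incubation": {
            "dFe": ConstantFlux(rate=0.0),
            "H2S": SaturatingFlux(plateau=7.0, timescale=10.0),
            "dAs": ConstantFlux(rate=0.0),
        },
        "schedule_weeks": 7,
        "solids_loss": {"dAs": 0.135, "dFe": -45.4},
    },
}

#: Solid-phase baseline (umol g-1) for the ascorbate-extractable pools; slices
#: at 0.5 cm (0-6 cm) and 1 cm (6-12 cm) resolution.
_SOLIDS_BASE = {
    "dAs": [0.30, 0.28, 0.22, 0.18, 0.15, 0.12] + [0.10] * 6 + [0.08] * 6,
    "dFe": [180.0, 150.0, 120.0, 90.0, 70.0, 55.0] + [45.0] * 6 + [35.0] * 6,
}
_SOLIDS_TOPS = [i * 0.005 for i in range(12)] + [0.06 + i * 0.01 for i in range(6)]
_SOLIDS_BOTS = [t + 0.005 for t in _SOLIDS_TOPS[:12]] + [
    t + 0.01 for t in _SOLIDS_TOPS[12:]
]


def _make_solids(
    species: str, loss_mmol_m2: float, props: SedimentProperties, campaign: str
) -> tuple[SolidPhaseProfile, SolidPhaseProfile]:
    """Before/after solid profiles with the prescribed 0-1 cm inventory loss."""
    base = np.array(_SOLIDS_BASE[species], dtype=float)
    # distribute the loss uniformly over the two 0-1 cm slices
    factor = (1.0 - props.porosity) * props.solid_density * 1.0e3  # mmol m-2 per (umol/g * m)
    delta_c = loss_mmol_m2 / (factor * 0.01)
    after = base.copy()
    after[0] -= delta_c
    after[1] -= delta_c
    if np.any(after < 0.0):
        raise DataError(
            f"prescribed {species} inventory change exceeds the baseline pool"
        )
    common = dict(
        depth_tops=np.array(_SOLIDS_TOPS),
        depth_bots=np.array(_SOLIDS_BOTS),
        extraction="ascorbate",
        campaign=campaign,
    )
    before = SolidPhaseProfile(
        species=species, concentrations=base, core_id="before", **common
    )
    after_p = SolidPhaseProfile(
        species=species, concentrations=after, core_id="after", **common
    )
    return before, after_p


def preset_names() -> list[str]:
    return sorted(PRESETS)


def make_scenario(
    preset: str,
    seed: int = 0,
    noise_cv: float = 0.0,
    registry: DiffusivityRegistry | None = None,
    as_species: str = DEFAULT_AS_SPECIES,
) -> Scenario:
    """Generate a full dataset (profiles, solids, incubations) for a preset.

    ``noise_cv`` applies multiplicative Gaussian noise to the pore-water
    profiles and incubation concentrations; microsensor templates and solids
    stay noiseless so the feature truth is exact.
    """
    if preset not in PRESETS:
        raise DataError(
            f"unknown preset {preset!r}; available: {', '.join(preset_names())}"
        )
    p = PRESETS[preset]
    props = SedimentProperties(**p["props"])
    rng = np.random.default_rng(seed)
    reg = registry if registry is not None else DiffusivityRegistry.default()

    truth = ScenarioTruth(name=preset)
    profiles: dict[str, DepthProfile] = {}

    detection_limit = 1.0
    profiles["O2"] = make_o2_profile(
        campaign=preset, core_id="sim", detection_limit=detection_limit, **p["o2"]
    )
    profiles["H2S"] = make_h2s_profile(
        sad=p["sad"] if p["sad"] is None or p["sad"] > 0 else 0.0,
        detection_limit=detection_limit,
        campaign=preset,
        core_id="sim",
    )
    profiles["pH"] = make_ph_profile(p["ph_control"], campaign=preset, core_id="sim")

    opd = p["o2"]["opd"] if p["o2"]["opd"] is not None else 0.0
    sad = p["sad"]
    truth.features = {
        "opd": opd,
        "sad": sad,
        "suboxic_thickness": None if sad is None else sad - opd,
        "ph_max_value": max(v for _, v in p["ph_control"]),
        "ph_min_value": min(v for _, v in p["ph_control"]),
    }

    for species in ("dFe", "dAs"):
        cfg = dict(p[species])
        if "peak_conc" in cfg:  # solve the rate that yields the target peak
            d0 = reg.d0(species, props.temperature, props.salinity, as_species)
            phi_ds = props.porosity * d0 / props.tortuosity_squared
            cfg["rate"] = (
                cfg.pop("peak_conc")
                * phi_ds
                / (cfg["upward_fraction"] * cfg["production_depth"])
            )
        profile, ptruth = make_steady_profile(
            species=species,
            production_rate=cfg["rate"],
            upward_fraction=cfg["upward_fraction"],
            production_depth=cfg["production_depth"],
            props=props,
            noise_cv=noise_cv,
            seed=int(rng.integers(2**31)),
            registry=reg,
            as_species=as_species,
            campaign=preset,
            core_id="sim",
        )
        profiles[species] = profile
        truth.profile_truths[species] = ptruth
        truth.production_rates[species] = cfg["rate"]
        truth.upward_fractions[species] = cfg["upward_fraction"]

    solids_before: dict[str, SolidPhaseProfile] = {}
    solids_after: dict[str, SolidPhaseProfile] = {}
    for species, loss in p["solids_loss"].items():
        before, after = _make_solids(species, loss, props, preset)
        solids_before[species] = before
        solids_after[species] = after
        truth.inventory_change_mmol_m2[species] = loss

    schedule = np.arange(0.0, 7.0 * p["schedule_weeks"] + 0.5, 7.0)
    incubations, ledger = simulate_incubation(
        p["incubation"],
        schedule,
        noise_cv=noise_cv,
        seed=int(rng.integers(2**31)),
        core_id="sim",
    )
    truth.incubation_flux = dict(p["incubation"])
    truth.schedule = schedule
    truth.released_umol = ledger
    area = DEFAULT_CORE_AREA
    truth.cumulative_mmol_m2 = {s: m / 1000.0 / area for s, m in ledger.items()}

    return Scenario(
        name=preset,
        props=props,
        profiles=profiles,
        solids_before=solids_before,
        solids_after=solids_after,
        incubations=incubations,
        truth=truth,
    )
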