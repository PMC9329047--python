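"""Benthic efflux estimation from closed-core incubations.

Cores are sampled sequentially (weekly in practice); after each sampling a
fraction of the overlying water is replaced.  The start inventory of each
interval accounts for that replacement:

    inventory_start = V_repl * C_repl + (V_olw - V_repl) * C_(t-1)

and the interval efflux is

    F(t) = (V_olw * C_t - inventory_start) / (A_core * dt)

with volumes in L, concentrations in mmol m-3 (µM) and fluxes in
mmol m-2 d-1.  Negative fluxes (uptake) are reported, never clipped; a QC
flag marks them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DataError, InsufficientDataError, OrderingError, VolumeError

#: Default core cross-section, m2 (28.3 cm2).
DEFAULT_CORE_AREA = 28.3e-4


@dataclass(frozen=True)
class IncubationEvent:
    """One sampling event.

    ``conc_end`` is the concentration measured *before* the replacement;
    ``v_repl`` and ``conc_repl`` describe the replacement applied directly
    after this sampling.
    """

    time: float  # d
    conc_end: float  # mmol m-3, pre-replacement
    v_olw: float  # L
    v_repl: float  # L
    conc_repl: float = 0.0  # mmol m-3

    def __post_init__(self) -> None:
        if self.v_olw <= 0.0:
            raise VolumeError(f"overlying volume must be > 0, got {self.v_olw}")
        if not 0.0 <= self.v_repl <= self.v_olw:
            raise VolumeError(
                f"replaced volume {self.v_repl} outside [0, {self.v_olw}]"
            )
        if self.conc_end < 0.0 or self.conc_repl < 0.0:
            raise DataError("concentrations must be >= 0")


@dataclass
class IncubationSeries:
    """Ordered sampling events for one core and one species."""

    core_id: str
    species: str
    events: list[IncubationEvent]
    core_area: float = DEFAULT_CORE_AREA

    def __post_init__(self) -> None:
        if self.core_area <= 0.0:
            raise DataError(f"core_area must be > 0, got {self.core_area}")
        times = [e.time for e in self.events]
        if any(t1 - t0 <= 0.0 for t0, t1 in zip(times, times[1:])):
            raise OrderingError(
                f"sampling times must be strictly increasing (core {self.core_id!r})"
            )

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class IntervalFlux:
    t_start: float
    t_end: float
    flux: float  # mmol m-2 d-1
    negative: bool = False  # QC flag: apparent uptake


@dataclass
class FluxSeries:
    """Per-interval fluxes tiling the incubation period."""

    core_id: str
    species: str
    intervals: list[IntervalFlux] = field(default_factory=list)

    @property
    def cumulative(self) -> float:
        return cumulative_flux(self)


def start_inventory(
    prev_conc: float, v_olw: float, v_repl: float, conc_repl: float
) -> float:
    """Overlying-water inventory (µmol) right after a replacement operation."""
    if not 0.0 <= v_repl <= v_olw:
        raise VolumeError(f"replaced volume {v_repl} outside [0, {v_olw}]")
    return v_repl * conc_repl + (v_olw - v_repl) * prev_conc


def interval_flux(series: IncubationSeries, index: int) -> float:
    """Efflux over the interval ending at event ``index`` (mmol m-2 d-1)."""
    if index < 1:
        raise InsufficientDataError("interval_flux needs a previous event (index >= 1)")
    prev = series.events[index - 1]
    cur = series.events[index]
    dt = cur.time - prev.time
    if dt <= 0.0:
        raise OrderingError(f"non-positive interval duration {dt}")
    start = start_inventory(prev.conc_end, prev.v_olw, prev.v_repl, prev.conc_repl)
    end = cur.v_olw * cur.conc_end
    # µmol / (m2 d) -> mmol m-2 d-1
    return (end - start) / (series.core_area * dt) / 1000.0


def interval_fluxes(series: IncubationSeries) -> FluxSeries:
    """All interval fluxes of a series, with negative-flux QC flags."""
    out = FluxSeries(core_id=series.core_id, species=series.species)
    for i in range(1, len(series)):
        f = interval_flux(series, i)
        out.intervals.append(
            IntervalFlux(
                t_start=series.events[i - 1].time,
                t_end=series.events[i].time,
                flux=f,
                negative=f < 0.0,
            )
        )
    return out


def cumulative_flux(fluxes: FluxSeries) -> float:
    """Time-integrated flux, sum of F * dt over all intervals (mmol m-2)."""
    return sum(iv.flux * (iv.t_end - iv.t_start) for iv in fluxes.intervals)


@dataclass(frozen=True)
class ReplicateStats:
    mean: float
    sd: float | None  # sample SD (n-1 denominator); None for n = 1
    n: int


def replicate_stats(values: list[float]) -> ReplicateStats:
    """Mean and sample standard deviation (n-1 denominator) of replicates."""
    n = len(values)
    if n == 0:
        raise InsufficientDataError("replicate_stats needs at least one value")
    mean = sum(values) / n
    if n == 1:
        return ReplicateStats(mean=mean, sd=None, n=1)
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return ReplicateStats(mean=mean, sd=math.sqrt(var), n=n)


def detect_onset(
    series: IncubationSeries, detection_limit: float = 1.0
) -> float | None:
    """Earliest sampling time whose concentration exceeds the detection limit."""
    for e in series.events:
        if e.conc_end > detection_limit:
            return e.time
    return None
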