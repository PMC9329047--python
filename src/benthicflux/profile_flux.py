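"""Pore-water and microsensor depth-profile analysis.

Gradient fitting, Fickian diffusive fluxes with tortuosity correction,
subsurface-peak production partitioning, and geochemical feature extraction
(oxygen penetration depth, sulfide appearance depth, pH extrema).

Depth is in m, positive downward with the sediment-water interface (SWI) at
0; negative depths denote overlying-water samples.  Fluxes are signed
positive downward, so a concentration increasing with depth yields a negative
(upward, toward-SWI) flux.  Depth windows are half-open intervals
``[top, bottom)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import physchem
from .errors import (
    AlignmentError,
    DataError,
    InsufficientDataError,
    NoInteriorPeakError,
)
from .physchem import DEFAULT_AS_SPECIES, DiffusivityRegistry, SedimentProperties

Window = tuple[float, float]

#: Default number of points fitted on each side of a feature of interest.
DEFAULT_WINDOW_POINTS = 4


@dataclass
class DepthProfile:
    """One solute's concentration vs. depth for one core.

    depths are strictly increasing (m, positive downward); concentrations are
    in mmol m-3 (= µM).  Small negative concentrations (instrument noise) are
    floored to zero on construction.
    """

    species: str
    depths: np.ndarray
    concentrations: np.ndarray
    core_id: str = ""
    campaign: str = ""
    detection_limit: float | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.depths.ndim != 1 or self.depths.shape != self.concentrations.shape:
            raise DataError("depths and concentrations must be 1-D and equal length")
        if len(self.depths) < 2:
            raise DataError("a profile needs at least 2 points")
        if not np.all(np.diff(self.depths) > 0):
            raise DataError(
                f"depths must be strictly increasing (core {self.core_id!r}, "
                f"species {self.species!r})"
            )
        self.concentrations = np.maximum(self.concentrations, 0.0)

    def __len__(self) -> int:
        return len(self.depths)

    def window_mask(self, window: Window) -> np.ndarray:
        top, bottom = window
        return (self.depths >= top) & (self.depths < bottom)


@dataclass(frozen=True)
class GradientFit:
    """OLS concentration gradient over a depth window."""

    slope: float  # mmol m-3 per m
    intercept: float
    stderr: float | None  # undefined (None) for exactly 2 points
    r_squared: float
    n_points: int
    window: Window


@dataclass(frozen=True)
class FluxResult:
    """Signed diffusive flux with full provenance.

    ``flux = -porosity * (d0 / tortuosity_squared) * slope``; positive
    downward.
    """

    flux: float  # mmol m-2 d-1
    slope: float
    slope_stderr: float | None
    r_squared: float
    window: Window
    n_points: int
    species: str
    registry_species: str
    d0: float
    porosity: float
    tortuosity_squared: float


@dataclass(frozen=True)
class PeakPartition:
    """Production rate at a subsurface maximum, split into up/down fluxes."""

    production: float  # mmol m-2 d-1, |J_above| + |J_below|
    upward_fraction: float
    downward_fraction: float
    peak_depth: float
    flux_above: FluxResult
    flux_below: FluxResult


@dataclass(frozen=True)
class ProfileFeatures:
    """Microsensor-derived geochemical features; None = undefined beyond profile."""

    opd: float | None
    sad: float | None
    suboxic_thickness: float | None
    ph_max_value: float | None = None
    ph_max_depth: float | None = None
    ph_min_value: float | None = None
    ph_min_depth: float | None = None


def _ols(x: np.ndarray, y: np.ndarray, window: Window) -> GradientFit:
    n = len(x)
    xm = x.mean()
    ym = y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise InsufficientDataError("window has no depth spread")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r_squared = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    stderr = None
    if n > 2:
        stderr = float(np.sqrt(max(ss_res, 0.0) / (n - 2) / sxx))
    return GradientFit(slope, float(intercept), stderr, r_squared, n, window)


def fit_gradient(profile: DepthProfile, window: Window) -> GradientFit:
    """OLS slope of concentration vs. depth over ``[top, bottom)``.

    The standard error is reported as None for exactly two points; a constant
    profile reports r² = 0 by convention.
    """
    mask = profile.window_mask(window)
    if int(mask.sum()) < 2:
        raise InsufficientDataError(
            f"window {window} contains {int(mask.sum())} point(s); need >= 2"
        )
    return _ols(profile.depths[mask], profile.concentrations[mask], window)


def _flux_from_fit(
    fit: GradientFit,
    profile: DepthProfile,
    props: SedimentProperties,
    registry: DiffusivityRegistry | None,
    as_species: str,
) -> FluxResult:
    reg = registry if registry is not None else DiffusivityRegistry.default()
    registry_species = physchem.resolve_species(profile.species, as_species)
    d0 = reg.d0(profile.species, props.temperature, props.salinity, as_species)
    theta2 = props.tortuosity_squared
    flux = -props.porosity * (d0 / theta2) * fit.slope
    return FluxResult(
        flux=flux,
        slope=fit.slope,
        slope_stderr=fit.stderr,
        r_squared=fit.r_squared,
        window=fit.window,
        n_points=fit.n_points,
        species=profile.species,
        registry_species=registry_species,
        d0=d0,
        porosity=props.porosity,
        tortuosity_squared=theta2,
    )


def diffusive_flux(
    profile: DepthProfile,
    props: SedimentProperties,
    window: Window,
    registry: DiffusivityRegistry | None = None,
    as_species: str = DEFAULT_AS_SPECIES,
) -> FluxResult:
    """Fickian diffusive flux from a linear fit over a depth window.

    ``J = -porosity * (D0(S, T) / theta2) * dC/dx``, positive downward.
    """
    fit = fit_gradient(profile, window)
    return _flux_from_fit(fit, profile, props, registry, as_species)


def _fit_indices(
    profile: DepthProfile,
    props: SedimentProperties,
    idx: np.ndarray,
    registry: DiffusivityRegistry | None,
    as_species: str,
) -> FluxResult:
    x = profile.depths[idx]
    y = profile.concentrations[idx]
    # half-open label for provenance; the points actually used are idx
    window = (float(x[0]), float(np.nextafter(x[-1], np.inf)))
    fit = _ols(x, y, window)
    return _flux_from_fit(fit, profile, props, registry, as_species)


def peak_partition(
    profile: DepthProfile,
    props: SedimentProperties,
    peak_window_size: int = DEFAULT_WINDOW_POINTS,
    registry: DiffusivityRegistry | None = None,
    as_species: str = DEFAULT_AS_SPECIES,
) -> PeakPartition:
    """Production rate at an interior concentration maximum.

    The production rate is the sum of the absolute diffusive fluxes fitted
    over the ``peak_window_size`` points immediately above and below the
    maximum (the peak point is included on both sides); the upward fraction
    is the share of that production leaving through the upper limb.  Ties at
    the maximum are broken toward greater depth.  A maximum at either end of
    the profile raises :class:`NoInteriorPeakError`.
    """
    if peak_window_size < 2:
        raise InsufficientDataError("peak_window_size must be >= 2")
    c = profile.concentrations
    peak_idx = int(np.flatnonzero(c == c.max())[-1])  # deepest tied maximum
    if peak_idx == 0 or peak_idx == len(c) - 1:
        raise NoInteriorPeakError(
            f"profile maximum at boundary depth {profile.depths[peak_idx]:.4g} m; "
            "no interior peak"
        )
    n_up = min(peak_window_size, peak_idx + 1)
    n_down = min(peak_window_size, len(c) - peak_idx)
    above = np.arange(peak_idx - n_up + 1, peak_idx + 1)
    below = np.arange(peak_idx, peak_idx + n_down)
    j_above = _fit_indices(profile, props, above, registry, as_species)
    j_below = _fit_indices(profile, props, below, registry, as_species)
    production = abs(j_above.flux) + abs(j_below.flux)
    if production == 0.0:
        raise NoInteriorPeakError("zero gradient on both sides of the maximum")
    upward = abs(j_above.flux) / production
    return PeakPartition(
        production=production,
        upward_fraction=upward,
        downward_fraction=1.0 - upward,
        peak_depth=float(profile.depths[peak_idx]),
        flux_above=j_above,
        flux_below=j_below,
    )


def _first_downward_crossing(
    depths: np.ndarray, conc: np.ndarray, limit: float
) -> float | None:
    """Shallowest depth where conc first falls below ``limit`` (interpolated).

    Returns max(first depth, 0) when the profile starts below the limit
    (the solute is absent from the interface), None when it never falls
    below the limit within the profile.
    """
    if conc[0] < limit:
        return max(float(depths[0]), 0.0)
    for i in range(len(conc) - 1):
        if conc[i] >= limit and conc[i + 1] < limit:
            frac = (conc[i] - limit) / (conc[i] - conc[i + 1])
            return float(depths[i] + frac * (depths[i + 1] - depths[i]))
    return None


def _first_upward_crossing(
    depths: np.ndarray, conc: np.ndarray, limit: float
) -> float | None:
    """Shallowest depth where conc first exceeds ``limit`` (interpolated)."""
    if conc[0] > limit:
        return max(float(depths[0]), 0.0)
    for i in range(len(conc) - 1):
        if conc[i] <= limit and conc[i + 1] > limit:
            frac = (limit - conc[i]) / (conc[i + 1] - conc[i])
            return float(depths[i] + frac * (depths[i + 1] - depths[i]))
    return None


def extract_features(
    o2: DepthProfile,
    h2s: DepthProfile,
    ph: DepthProfile,
    detection_limit: float = 1.0,
) -> ProfileFeatures:
    """Extract OPD, SAD, suboxic-zone thickness and pH extrema.

    OPD is the shallowest depth where O2 first falls below the detection
    limit and SAD the shallowest depth where sulfide first exceeds it, both
    linearly interpolated between bracketing samples.  Features that are not
    bracketed within the profile are reported as None (undefined beyond
    profile), not as errors.
    """
    if detection_limit <= 0.0:
        raise DataError("detection_limit must be > 0")
    top = max(p.depths[0] for p in (o2, h2s, ph))
    bottom = min(p.depths[-1] for p in (o2, h2s, ph))
    if top >= bottom:
        raise AlignmentError("O2, H2S and pH profiles have no overlapping depth range")
    opd = _first_downward_crossing(o2.depths, o2.concentrations, detection_limit)
    sad = _first_upward_crossing(h2s.depths, h2s.concentrations, detection_limit)
    suboxic = None if opd is None or sad is None else sad - opd
    i_max = int(np.argmax(ph.concentrations))
    i_min = int(np.argmin(ph.concentrations))
    return ProfileFeatures(
        opd=opd,
        sad=sad,
        suboxic_thickness=suboxic,
        ph_max_value=float(ph.concentrations[i_max]),
        ph_max_depth=float(ph.depths[i_max]),
        ph_min_value=float(ph.concentrations[i_min]),
        ph_min_depth=float(ph.depths[i_min]),
    )
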