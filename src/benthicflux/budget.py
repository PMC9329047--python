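"""Derived budgets: oxic-zone trapping, water-column dilution, sorption release.

Budget operations work on summary quantities (production rates, cumulative
fluxes, adsorbed concentrations) rather than raw profiles, and carry QC flags
and method labels instead of failing on physically awkward inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DataError, RangeError
from .physchem import SedimentProperties

#: Cumulative fluxes below this value (mmol m-2) count as "no detectable
#: flux" and are excluded from the default dilution range.
DETECTABLE_CUMULATIVE_FLUX = 0.01

#: US EPA acute marine exposure guideline for arsenite, nM.
DEFAULT_GUIDELINE_NM = 920.0


@dataclass(frozen=True)
class EscapeFlux:
    escape: float  # µmol m-2 d-1 potentially reaching the water column
    upward: float  # µmol m-2 d-1 diffusing toward the interface
    trapped: float  # µmol m-2 d-1 retained in the oxic layer
    over_trapped: bool  # QC flag: trapping exceeded the upward supply


def escape_flux(
    production: float, upward_fraction: float, trapped: float
) -> EscapeFlux:
    """Flux escaping to the water column after oxic-zone trapping.

    ``upward = production * upward_fraction``; escape is the upward flux
    minus the trapped flux, floored at zero with an over-trapping QC flag
    (trapping cannot exceed supply).
    """
    if production < 0.0 or trapped < 0.0:
        raise RangeError("production and trapped fluxes must be >= 0")
    if not 0.0 <= upward_fraction <= 1.0:
        raise RangeError(f"upward_fraction must be in [0, 1], got {upward_fraction}")
    upward = production * upward_fraction
    over = trapped > upward
    return EscapeFlux(
        escape=0.0 if over else upward - trapped,
        upward=upward,
        trapped=trapped,
        over_trapped=over,
    )


def mixed_layer_concentration(cumulative_flux: float, height: float) -> float:
    """Concentration (nM) after diluting a cumulative flux over a mixed layer.

    ``cumulative_flux`` is in mmol m-2 and ``height`` in m; the quotient is
    in mmol m-3 (= µM) and is reported in nM.
    """
    if height <= 0.0:
        raise RangeError(f"mixed-layer height must be > 0, got {height}")
    return cumulative_flux / height * 1000.0


def dilution_range(
    cumulative_fluxes: list[float],
    height: float,
    min_detectable: float = DETECTABLE_CUMULATIVE_FLUX,
) -> tuple[float, float]:
    """(min, max) mixed-layer concentration in nM over detectable cores.

    Cores whose cumulative flux falls below ``min_detectable`` (mmol m-2)
    are flagged "no detectable flux" and excluded.
    """
    detectable = [f for f in cumulative_fluxes if f >= min_detectable]
    if not detectable:
        raise DataError("no cores with detectable cumulative flux")
    return (
        mixed_layer_concentration(min(detectable), height),
        mixed_layer_concentration(max(detectable), height),
    )


def sorption_release(
    adsorbed_conc: float,
    capacity_loss_fraction: float,
    props: SedimentProperties,
) -> float:
    """Pore-water concentration rise (µM) from a loss of sorption capacity.

    A fraction of the adsorbed pool (µmol per g solid) is transferred to the
    pore water: ``dC = fraction * adsorbed * (1 - phi) * rho_s / phi`` with
    units resolved to µmol per L pore water (= µM).
    """
    if adsorbed_conc < 0.0:
        raise RangeError("adsorbed_conc must be >= 0")
    if not 0.0 <= capacity_loss_fraction <= 1.0:
        raise RangeError("capacity_loss_fraction must be in [0, 1]")
    phi = props.porosity
    # umol/g * g/cm3 -> umol/cm3 pore water; * 1000 cm3/L -> uM
    return (
        capacity_loss_fraction
        * adsorbed_conc
        * (1.0 - phi)
        * props.solid_density
        / phi
        * 1000.0
    )


@dataclass(frozen=True)
class ElementRatio:
    ratio: float
    method: str
    caveat: str = (
        "summary-level aggregation of cumulative fluxes; not equivalent to a "
        "regression of weekly fluxes"
    )


def element_ratio(
    cumulative_a: list[float],
    cumulative_b: list[float],
    method: str = "ratio-of-sums",
) -> ElementRatio:
    """Aggregate ratio of two sets of per-core cumulative fluxes.

    ``ratio-of-sums`` divides the summed numerator by the summed denominator;
    ``per-core-mean`` averages the per-core ratios.  The method label is
    recorded in the result.
    """
    if len(cumulative_a) != len(cumulative_b):
        raise DataError(
            f"mismatched lengths: {len(cumulative_a)} vs {len(cumulative_b)}"
        )
    if len(cumulative_a) == 0:
        raise DataError("element_ratio needs at least one core")
    if any(b <= 0.0 for b in cumulative_b):
        raise DataError("denominator cumulative fluxes must be > 0")
    if method == "ratio-of-sums":
        ratio = sum(cumulative_a) / sum(cumulative_b)
    elif method == "per-core-mean":
        ratios = [a / b for a, b in zip(cumulative_a, cumulative_b)]
        ratio = sum(ratios) / len(ratios)
    else:
        raise DataError(f"unknown method {method!r}")
    return ElementRatio(ratio=ratio, method=method)
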