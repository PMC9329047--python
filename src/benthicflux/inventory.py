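"""Solid-phase inventory integration.

An inventory over a depth interval is

    INV = integral of (1 - porosity) * rho_s * C_solid dx

with C_solid in µmol g-1 dry weight, rho_s in g cm-3, depths in m and the
result in mmol m-2.  Profiles declare either contiguous slice boundaries
(rectangle rule per slice) or slice midpoints (trapezoid rule on the
interpolated profile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CoverageError, DataError
from .physchem import SedimentProperties

# (1-phi)[-] * rho_s[g cm-3 -> 1e6 g m-3] * C[umol g-1 -> 1e-3 mmol g-1] * dx[m]
_UNIT_FACTOR = 1.0e3


@dataclass
class SolidPhaseProfile:
    """Solid-phase concentration profile from a sectioned core.

    Either build from slice boundaries (``depth_tops``/``depth_bots``, the
    default for sectioned cores) or from midpoints via :meth:`from_midpoints`.
    """

    species: str
    depth_tops: np.ndarray
    depth_bots: np.ndarray
    concentrations: np.ndarray  # umol g-1 dry weight
    extraction: str = ""
    core_id: str = ""
    campaign: str = ""

    def __post_init__(self) -> None:
        self.depth_tops = np.asarray(self.depth_tops, dtype=float)
        self.depth_bots = np.asarray(self.depth_bots, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if not (
            self.depth_tops.shape
            == self.depth_bots.shape
            == self.concentrations.shape
        ):
            raise DataError("depth_tops, depth_bots and concentrations must match")
        if np.any(self.depth_bots <= self.depth_tops):
            raise DataError("each slice needs depth_bot > depth_top")
        if not np.all(np.diff(self.depth_tops) > 0):
            raise DataError("slices must be ordered by increasing depth")
        if np.any(self.depth_tops[1:] < self.depth_bots[:-1] - 1e-9):
            raise DataError("slices must not overlap")
        if np.any(self.concentrations < 0):
            raise DataError("solid-phase concentrations must be >= 0")

    @classmethod
    def from_midpoints(
        cls,
        species: str,
        midpoints,
        concentrations,
        slice_thickness: float | None = None,
        **kwargs,
    ) -> "SolidPhaseProfile":
        """Build contiguous slices around declared midpoints.

        With a uniform ``slice_thickness`` the slices are centred on the
        midpoints; otherwise boundaries are placed halfway between adjacent
        midpoints (end slices mirror their inner half-width).
        """
        mid = np.asarray(midpoints, dtype=float)
        if slice_thickness is not None:
            half = slice_thickness / 2.0
            tops, bots = mid - half, mid + half
        else:
            inner = (mid[:-1] + mid[1:]) / 2.0
            tops = np.concatenate([[2 * mid[0] - inner[0]], inner])
            bots = np.concatenate([inner, [2 * mid[-1] - inner[-1]]])
        return cls(species, tops, bots, concentrations, **kwargs)

    @property
    def coverage(self) -> tuple[float, float]:
        return float(self.depth_tops[0]), float(self.depth_bots[-1])


def solid_inventory(
    profile: SolidPhaseProfile,
    props: SedimentProperties,
    x_up: float,
    x_down: float,
) -> float:
    """Depth-integrated solid-phase inventory over [x_up, x_down], mmol m-2.

    Uses the depth-averaged porosity and solid density from ``props`` and a
    slice-wise rectangle rule; raises :class:`CoverageError` if the interval
    is not fully tiled by the declared slices.
    """
    if not x_up < x_down:
        raise CoverageError(f"need x_up < x_down, got [{x_up}, {x_down}]")
    lo, hi = profile.coverage
    if x_up < lo - 1e-12 or x_down > hi + 1e-12:
        raise CoverageError(
            f"interval [{x_up}, {x_down}] m outside profile coverage [{lo}, {hi}] m"
        )
    overlap = np.minimum(profile.depth_bots, x_down) - np.maximum(
        profile.depth_tops, x_up
    )
    overlap = np.maximum(overlap, 0.0)
    if abs(float(overlap.sum()) - (x_down - x_up)) > 1e-9:
        raise CoverageError(
            f"interval [{x_up}, {x_down}] m crosses a gap between slices"
        )
    solid_fraction = (1.0 - props.porosity) * props.solid_density
    return float(
        np.sum(solid_fraction * profile.concentrations * overlap) * _UNIT_FACTOR
    )


def inventory_change(
    before: SolidPhaseProfile,
    after: SolidPhaseProfile,
    props: SedimentProperties,
    x_up: float,
    x_down: float,
) -> float:
    """Inventory(before) - inventory(after); positive = loss from sediment."""
    return solid_inventory(before, props, x_up, x_down) - solid_inventory(
        after, props, x_up, x_down
    )
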