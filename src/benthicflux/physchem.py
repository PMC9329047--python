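"""Physical-chemistry primitives for sediment pore-water transport.

Canonical internal units used throughout the package:

* depth: m, positive downward, sediment-water interface (SWI) at 0
* concentration: mmol m⁻³ (numerically equal to µM)
* flux: mmol m⁻² d⁻¹, positive downward
* diffusion coefficient: m² d⁻¹
* solid-phase concentration: µmol g⁻¹ dry weight
* inventory: mmol m⁻²

Free-solution diffusion coefficients are evaluated from a per-species linear
relation in temperature, ``D0 = (m0 + m1*T) * 1e-6 cm2 s-1``, with constants
shipped as an editable registry table (``data/diffusion_coefficients.csv``).
The salinity dependence is applied as a Stokes-Einstein correction, scaling by
the ratio of freshwater to seawater dynamic viscosity at the same temperature
(Sharqawy-style correlation, see :func:`seawater_viscosity`).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources

from .errors import InconsistentDataError, RangeError, UnknownSpeciesError

#: 1 cm2 s-1 = 1e-4 m2 s-1 * 86400 s d-1 = 8.64 m2 d-1
CM2_PER_S_TO_M2_PER_D = 8.64

TEMPERATURE_RANGE = (-2.0, 40.0)
SALINITY_RANGE = (0.0, 42.0)

#: Default arsenate species used when a profile is labelled generically
#: ("dAs", "As").  The assumed As species is a configuration choice and is
#: echoed in flux provenance; switch to "H2AsO4-" or "H3AsO3" as needed.
DEFAULT_AS_SPECIES = "HAsO4--"

_ALIASES = {
    "dfe": "Fe2+",
    "fe": "Fe2+",
    "fe2+": "Fe2+",
    "dmn": "Mn2+",
    "mn": "Mn2+",
    "mn2+": "Mn2+",
    "h2s": "H2S",
    "sumh2s": "H2S",
    "hs-": "HS-",
    "o2": "O2",
    "oxygen": "O2",
    "das": None,  # resolved through the as_species switch
    "as": None,
    "haso4--": "HAsO4--",
    "h2aso4-": "H2AsO4-",
    "h3aso3": "H3AsO3",
}


def resolve_species(name: str, as_species: str = DEFAULT_AS_SPECIES) -> str:
    """Map a data-file species label to a registry species name.

    Generic arsenic labels ("dAs", "As") resolve to ``as_species``; unknown
    labels pass through unchanged (the registry lookup will then raise).
    """
    canonical = _ALIASES.get(name.strip().lower(), name.strip())
    if canonical is None:
        canonical = as_species
    return canonical


def _check_temperature(temperature: float) -> None:
    lo, hi = TEMPERATURE_RANGE
    if not lo <= temperature <= hi:
        raise RangeError(
            f"temperature {temperature} degC outside valid range [{lo}, {hi}]"
        )


def _check_salinity(salinity: float) -> None:
    lo, hi = SALINITY_RANGE
    if not lo <= salinity <= hi:
        raise RangeError(f"salinity {salinity} outside valid range [{lo}, {hi}]")


@dataclass(frozen=True)
class SedimentProperties:
    """Bulk sediment properties controlling unit-bearing conversions.

    Parameters
    ----------
    porosity:
        Volume fraction of pore water, 0 < porosity < 1 (depth-averaged).
    solid_density:
        Dry solid density in g cm-3 (> 1).
    salinity:
        Practical salinity of the pore water (dimensionless).
    temperature:
        In-situ temperature in degC.
    """

    porosity: float
    solid_density: float = 2.6
    salinity: float = 30.0
    temperature: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise RangeError(f"porosity must be in (0, 1), got {self.porosity}")
        if self.solid_density <= 1.0:
            raise RangeError(
                f"solid_density must exceed 1 g cm-3, got {self.solid_density}"
            )
        _check_salinity(self.salinity)
        _check_temperature(self.temperature)

    @property
    def tortuosity_squared(self) -> float:
        return tortuosity_squared(self.porosity)


def tortuosity_squared(porosity: float) -> float:
    """Tortuosity correction factor ``theta2 = 1 - 2 ln(porosity)``.

    >= 1 for any admissible porosity, equal to 1 only for porosity 1, and
    strictly decreasing in porosity.
    """
    if not 0.0 < porosity <= 1.0:
        raise RangeError(f"porosity must be in (0, 1], got {porosity}")
    return 1.0 - 2.0 * math.log(porosity)


def water_viscosity(temperature: float) -> float:
    """Dynamic viscosity of pure water in Pa s (Sharqawy et al. 2010 fit)."""
    return 4.2844e-5 + 1.0 / (0.157 * (temperature + 64.993) ** 2 - 91.296)


def seawater_viscosity(temperature: float, salinity: float) -> float:
    """Dynamic viscosity of seawater in Pa s.

    Correlation of Sharqawy, Lienhard & Zubair (2010), with practical
    salinity treated as g salt per kg solution.  Valid for 0-180 degC and
    salinity 0-150; monotonically increasing in salinity.
    """
    s = salinity / 1000.0  # kg salt per kg solution
    a = 1.541 + 1.998e-2 * temperature - 9.52e-5 * temperature**2
    b = 7.974 - 7.561e-2 * temperature + 4.724e-4 * temperature**2
    return water_viscosity(temperature) * (1.0 + a * s + b * s * s)


def viscosity_ratio(temperature: float, salinity: float) -> float:
    """Freshwater-to-seawater dynamic-viscosity ratio (<= 1 for salinity > 0)."""
    return water_viscosity(temperature) / seawater_viscosity(temperature, salinity)


@dataclass(frozen=True)
class DiffusivityEntry:
    """Linear-in-temperature free-solution diffusivity, 1e-6 cm2 s-1 scale."""

    species: str
    m0: float
    m1: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.m0 <= 0.0:
            raise RangeError(f"{self.species}: intercept m0 must be > 0, got {self.m0}")
        lo, hi = TEMPERATURE_RANGE
        if self.m0 + self.m1 * lo <= 0.0 or self.m0 + self.m1 * hi <= 0.0:
            raise RangeError(
                f"{self.species}: D0 not positive over the valid temperature range"
            )


class DiffusivityRegistry:
    """Per-species free-solution diffusivity constants.

    The default registry is loaded from the packaged delimited table and can
    be replaced by :meth:`from_csv` to override constants.
    """

    _default: "DiffusivityRegistry | None" = None

    def __init__(self, entries: list[DiffusivityEntry]):
        self._entries = {e.species: e for e in entries}

    @classmethod
    def from_csv(cls, path) -> "DiffusivityRegistry":
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    DiffusivityEntry(
                        species=row["species"].strip(),
                        m0=float(row["m0"]),
                        m1=float(row["m1"]),
                        note=row.get("note", "").strip(),
                    )
                )
        return cls(entries)

    @classmethod
    def default(cls) -> "DiffusivityRegistry":
        if cls._default is None:
            ref = resources.files("benthicflux.data") / "diffusion_coefficients.csv"
            with resources.as_file(ref) as path:
                cls._default = cls.from_csv(path)
        return cls._default

    @property
    def species(self) -> list[str]:
        return sorted(self._entries)

    def __contains__(self, species: str) -> bool:
        return resolve_species(species) in self._entries

    def entry(
        self, species: str, as_species: str = DEFAULT_AS_SPECIES
    ) -> DiffusivityEntry:
        canonical = resolve_species(species, as_species)
        try:
            return self._entries[canonical]
        except KeyError:
            raise UnknownSpeciesError(
                f"unknown species {species!r} (resolved {canonical!r}); "
                f"registry contains: {', '.join(self.species)}"
            ) from None

    def d0(
        self,
        species: str,
        temperature: float,
        salinity: float,
        as_species: str = DEFAULT_AS_SPECIES,
    ) -> float:
        """Free-solution diffusion coefficient in m2 d-1 at (T, S)."""
        _check_temperature(temperature)
        _check_salinity(salinity)
        e = self.entry(species, as_species)
        d0_cm2_s = (e.m0 + e.m1 * temperature) * 1e-6
        return d0_cm2_s * CM2_PER_S_TO_M2_PER_D * viscosity_ratio(temperature, salinity)


def diffusion_coefficient(
    species: str,
    temperature: float,
    salinity: float,
    registry: DiffusivityRegistry | None = None,
    as_species: str = DEFAULT_AS_SPECIES,
) -> float:
    """Free-solution diffusion coefficient D0 in m2 d-1.

    Evaluates the registry's linear-in-temperature relation and applies the
    freshwater-to-seawater viscosity-ratio salinity correction; strictly
    increasing in temperature (for positive slope) and decreasing in salinity.
    """
    reg = registry if registry is not None else DiffusivityRegistry.default()
    return reg.d0(species, temperature, salinity, as_species)


def porosity_from_water_content(
    wet_mass: float,
    dry_mass: float,
    solid_density: float = 2.6,
    pore_water_density: float = 1.02,
    salinity: float = 0.0,
) -> float:
    """Porosity from wet/dry sediment masses, correcting for pore-water salt.

    The mass lost on drying is evaporated water only; the salt stays with the
    solids.  With mass salt fraction ``s = salinity / 1000``, the true
    pore-water mass is ``(wet - dry) / (1 - s)`` and the true solid mass is
    the dry mass minus the retained salt.  Porosity is the pore-water volume
    fraction of the two-phase mixture.
    """
    if dry_mass <= 0.0 or wet_mass < dry_mass:
        raise RangeError(
            f"need wet_mass >= dry_mass > 0, got wet={wet_mass}, dry={dry_mass}"
        )
    if solid_density <= 0.0 or pore_water_density <= 0.0:
        raise RangeError("densities must be positive")
    _check_salinity(salinity)
    s = salinity / 1000.0
    m_pw = (wet_mass - dry_mass) / (1.0 - s)
    m_solid = dry_mass - s * m_pw
    if m_solid <= 0.0:
        raise InconsistentDataError(
            "salt-corrected solid mass is not positive; check masses and salinity"
        )
    v_pw = m_pw / pore_water_density
    v_solid = m_solid / solid_density
    return v_pw / (v_pw + v_solid)
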