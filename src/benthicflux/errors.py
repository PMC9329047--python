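"""Exception hierarchy.

All package errors derive from :class:`BenthicfluxError` so callers can catch
one base class at pipeline boundaries.
"""


class BenthicfluxError(Exception):
    """Base class for all benthicflux errors."""


class RangeError(BenthicfluxError, ValueError):
    """A numeric argument is outside its physically valid range."""


class UnknownSpeciesError(BenthicfluxError, KeyError):
    """Species not found in the diffusivity registry."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class InconsistentDataError(BenthicfluxError, ValueError):
    """Inputs are mutually inconsistent (e.g. salt-corrected solid mass <= 0)."""


class InsufficientDataError(BenthicfluxError, ValueError):
    """Too few data points for the requested operation."""


class NoInteriorPeakError(BenthicfluxError, ValueError):
    """Profile maximum sits at a boundary; peak partitioning is undefined."""


class AlignmentError(BenthicfluxError, ValueError):
    """Depth ranges of co-analysed profiles do not overlap."""


class CoverageError(BenthicfluxError, ValueError):
    """Requested depth interval is not covered by the profile."""


class VolumeError(BenthicfluxError, ValueError):
    """Replaced volume exceeds the overlying-water volume."""


class OrderingError(BenthicfluxError, ValueError):
    """Sampling times are not strictly increasing."""


class SchemaError(BenthicfluxError, ValueError):
    """An input table is missing required columns."""


class DataError(BenthicfluxError, ValueError):
    """An input table contains invalid rows."""


class PipelineError(BenthicfluxError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
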