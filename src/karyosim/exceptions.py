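"""Exception hierarchy shared by the karyosim modules."""


class KaryosimError(Exception):
    """Base class for all package-specific errors."""


class GeometryFormatError(KaryosimError, ValueError):
    """A geometry table is malformed (e.g. a required column is missing)."""


class GeometryValidationError(KaryosimError, ValueError):
    """A geometry object violates its invariants (e.g. non-increasing times)."""


class TimeRangeError(KaryosimError, ValueError):
    """A query time lies outside the span of a geometry series."""


class GeometryTooNarrowError(KaryosimError, RuntimeError):
    """No primitive of the current geometry can host the particle radius."""


class DegenerateGeometryError(KaryosimError, RuntimeError):
    """Rejection sampling acceptance rate collapsed; geometry is degenerate."""


class SimulationError(KaryosimError, RuntimeError):
    """A particle simulation failed; carries the failing simulation time."""


class GenerationError(KaryosimError, RuntimeError):
    """The synthetic-geometry generator exhausted its retry budget."""


class DegenerateDataError(KaryosimError, ValueError):
    """Input data admit no meaningful estimate (e.g. zero IQR)."""
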