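"""Exception hierarchy for skategrf.

All domain errors derive from :class:`SkateGRFError` so callers can catch one
base class at pipeline boundaries.
"""


class SkateGRFError(Exception):
    """Base class for all skategrf errors."""


class InvalidParameterError(SkateGRFError, ValueError):
    """A numeric parameter violates its documented precondition."""


class InsufficientDataError(SkateGRFError, ValueError):
    """Too few samples / pairs / participants for the requested operation."""


class DegenerateSignalError(SkateGRFError, ValueError):
    """Signal structure prevents the operation (e.g. no noise floor)."""


class GeometryError(SkateGRFError, ValueError):
    """Degenerate marker geometry (coincident or collinear points)."""


class NearStationaryError(SkateGRFError, ValueError):
    """Horizontal CM speed too small to define the travel-aligned frame."""


class ResamplingError(SkateGRFError, ValueError):
    """Force/marker sampling rates are not compatible for synchronization."""


class EventOrderError(SkateGRFError, ValueError):
    """Blade contact/off events are not in their required order."""


class FitError(SkateGRFError, ValueError):
    """A regression cannot be fitted (zero variance, too few points)."""


class ContractError(SkateGRFError, ValueError):
    """An internal invariant was violated by caller-supplied data."""


class ConfigurationError(SkateGRFError, ValueError):
    """Invalid or incomplete configuration."""


class ParseError(SkateGRFError, ValueError):
    """A file could not be parsed; message carries the offending line."""
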