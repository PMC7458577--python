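"""Exception hierarchy for woundplanim.

All package-specific failures derive from :class:`WoundPlanimError` so callers
can catch one base class; subclasses additionally derive from the closest
builtin (``ValueError`` / ``IOError``) so generic handling keeps working.
"""


class WoundPlanimError(Exception):
    """Base class for all woundplanim errors."""


class InvalidParameterError(WoundPlanimError, ValueError):
    """A numeric parameter is outside its valid domain (e.g. radius <= 0)."""


class InvalidPolygonError(WoundPlanimError, ValueError):
    """A polygon has fewer than 3 vertices or is otherwise degenerate."""


class OutOfBoundsError(WoundPlanimError, ValueError):
    """A shape does not fit on the calibrated sheet with the required margin."""


class ImageFormatError(WoundPlanimError, IOError):
    """Unsupported or unreadable raster file."""


class DegenerateImageError(WoundPlanimError, ValueError):
    """Automatic thresholding is impossible (constant-intensity image)."""


class NoGridError(WoundPlanimError, ValueError):
    """Fewer than the minimum number of grid lines detected on an axis."""


class UnreliableGridError(WoundPlanimError, ValueError):
    """Detected grid line spacings are too irregular to trust."""


class OpenBoundaryError(WoundPlanimError, ValueError):
    """The traced curve does not enclose any interior region."""


class AmbiguousInteriorError(WoundPlanimError, ValueError):
    """More than one sizeable enclosed region was found.

    The candidate component areas (cm^2) are available as ``.areas_cm2``.
    """

    def __init__(self, message: str, areas_cm2=None):
        super().__init__(message)
        self.areas_cm2 = list(areas_cm2) if areas_cm2 is not None else []


class NoRegionError(WoundPlanimError, ValueError):
    """An operation requiring a non-empty region received an empty mask."""


class InsufficientSeriesError(WoundPlanimError, ValueError):
    """A healing series is too short for the requested computation."""


class InvalidBaselineError(WoundPlanimError, ValueError):
    """Baseline area S0 must be strictly positive."""


class InvalidReferenceError(WoundPlanimError, ValueError):
    """Reference area for a percent difference must be strictly positive."""


class IncompleteDataError(WoundPlanimError, ValueError):
    """A wound is missing the reference method's measurement."""


class UndefinedCorrelationError(WoundPlanimError, ValueError):
    """Pearson correlation is undefined (zero variance or too few points)."""
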