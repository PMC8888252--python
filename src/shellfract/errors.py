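"""Exception hierarchy for shellfract.

All exceptions raised deliberately by the package derive from
:class:`ShellfractError`, so callers can catch pipeline-level failures with a
single except clause while still seeing precise subclasses in messages.
"""


class ShellfractError(Exception):
    """Base class for all shellfract errors."""


class STLFormatError(ShellfractError):
    """Raised for truncated or garbled STL files; message names a byte offset."""


class EmptyMeshError(ShellfractError):
    """Raised when an STL file or mesh contains zero triangles."""


class ParameterError(ShellfractError):
    """Raised for invalid user-supplied parameters."""


class GeometryError(ShellfractError):
    """Raised for degenerate geometry (e.g. a mesh with a point bounding box)."""


class InsufficientScalesError(ShellfractError):
    """Raised when a fit is requested on fewer scales than the estimator needs."""


class DegenerateCohortError(ShellfractError):
    """Raised when cohort statistics are requested on a degenerate cohort."""


class DegenerateConfigurationError(ShellfractError):
    """Raised for landmark configurations unusable for alignment (collinear, < 3 points)."""
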