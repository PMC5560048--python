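"""Exception hierarchy for jointquant.

All errors derive from :class:`JointQuantError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
distinct failure contracts of the pipeline stages.
"""


class JointQuantError(Exception):
    """Base class for all jointquant errors."""


class CalibrationError(JointQuantError):
    """Missing or invalid voxel calibration (sidecar absent, non-positive sizes)."""


class FormatError(JointQuantError):
    """File layout inconsistent with its declared metadata."""


class GeometryError(JointQuantError):
    """Degenerate point configuration (too few points, collinear or coplanar)."""


class DegenerateHistogramError(JointQuantError):
    """Histogram thresholding asked of a constant-intensity sample."""


class UndefinedBaselineError(JointQuantError):
    """Percentage change requested against a non-positive baseline."""


class InsufficientDataError(JointQuantError):
    """Statistical routine called with fewer observations than it requires."""


class DomainError(JointQuantError):
    """Arguments outside an operation's mathematical domain."""
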