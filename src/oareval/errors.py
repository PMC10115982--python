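"""Exception hierarchy for oareval.

Every error raised deliberately by this package derives from
:class:`OarEvalError`, so callers can catch the package's failures without
masking genuine bugs.
"""


class OarEvalError(Exception):
    """Base class for all oareval errors."""


class InvalidGeometryError(OarEvalError):
    """A contour or mask violates a geometric precondition (e.g. < 3 vertices)."""


class UnsupportedOrientationError(OarEvalError):
    """Input geometry is not axis-aligned / axial-planar within tolerance."""


class GridMismatchError(OarEvalError):
    """Two rasters that must share a voxel grid do not."""


class UndefinedMetricError(OarEvalError):
    """A metric was requested on inputs for which it is undefined (empty mask)."""


class InvalidParameterError(OarEvalError):
    """A metric parameter (tolerance, percentile, margin) is out of range."""


class UndefinedDVHError(OarEvalError):
    """A DVH was requested for an empty evaluation region."""


class InvalidQueryError(OarEvalError):
    """A DVH statistic query is inconsistent with the curve (e.g. Dxcc, x > V)."""


class EmptyTemplateError(OarEvalError):
    """A plan-quality template resolves to no scoreable objectives."""


class InsufficientDataError(OarEvalError):
    """A statistic needs more observations than were supplied."""


class PairingError(OarEvalError):
    """Paired samples could not be aligned (length or id mismatch)."""


class SpecError(OarEvalError):
    """A synthetic phantom or perturbation specification is invalid."""
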