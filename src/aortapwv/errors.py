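"""Exception hierarchy.

All package errors derive from :class:`AortaPWVError` so callers can catch one
base class; the pipeline additionally distinguishes per-curve foot-detection
failures (:class:`FootDetectionError`) which are recoverable by excluding the
affected site from a trajectory fit.
"""


class AortaPWVError(Exception):
    """Base class for all aortapwv errors."""


class ConfigError(AortaPWVError):
    """Invalid or internally inconsistent configuration / ground truth."""


class SegmentationError(AortaPWVError):
    """Multi-cycle recording cannot be split into R-R cycles."""


class FootDetectionError(AortaPWVError):
    """Base class for failures of systolic wave-front onset detection."""


class NoUpslopeError(FootDetectionError):
    """No systolic upslope: flat curve or range below the noise floor."""


class InsufficientSamplesError(FootDetectionError):
    """Fewer than 3 usable fit points in the 20-80% upslope band."""


class NonPhysicalSlopeError(FootDetectionError):
    """Fitted systolic upslope is not positive."""


class AggregationError(AortaPWVError):
    """No valid per-cycle onset estimate to aggregate."""


class GeometryError(AortaPWVError):
    """Invalid geometric input (non-unit direction, out-of-extent chord, ...)."""


class DegenerateGeometryError(GeometryError):
    """Degenerate lumen geometry: self-intersection, zero width, <3 points."""


class NonPhysicalPropagationError(AortaPWVError):
    """Transit time or distance-time slope implies non-positive wave speed."""


class InsufficientSitesError(AortaPWVError):
    """Fewer than 2 valid measurement sites for a trajectory fit."""


class SiteMatchError(AortaPWVError):
    """No pullback recording close enough to a requested site."""


class DomainError(AortaPWVError):
    """Argument outside the physical domain of a model equation."""


class StatisticsError(AortaPWVError):
    """Base class for agreement-statistics errors."""


class SampleSizeError(StatisticsError):
    """Too few paired subjects for the requested statistic."""


class DegenerateStatisticsError(StatisticsError):
    """Statistic undefined (zero variance, zero reference value, ...)."""


class PairingError(StatisticsError):
    """Paired series do not share the same subjects / reference values."""


class ManifestError(AortaPWVError):
    """Study manifest references missing or inconsistent data streams."""
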