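"""Exception hierarchy for rfqus.

All package-specific failures derive from :class:`RFQUSError` so callers can
catch one base class; most also subclass the closest builtin (ValueError,
IndexError) so generic handling keeps working.
"""


class RFQUSError(Exception):
    """Base class for all rfqus errors."""


class MalformedFileError(RFQUSError, ValueError):
    """A binary RF file does not match the size implied by its metadata."""


class SchemaError(RFQUSError, ValueError):
    """A sidecar metadata record is missing or has invalid fields."""


class InvalidSignalError(RFQUSError, ValueError):
    """An RF array contains non-finite samples."""


class DegenerateImageError(RFQUSError, ValueError):
    """An image is degenerate for the requested operation (e.g. all-zero)."""


class BoundsError(RFQUSError, IndexError):
    """An ROI or index extends beyond the addressed array."""


class ROITooSmallError(RFQUSError, ValueError):
    """An ROI is too small for the requested window/patch geometry."""


class ConfigError(RFQUSError, ValueError):
    """A configuration value is inconsistent with the data it is applied to."""


class DegenerateWindowError(RFQUSError, ValueError):
    """A local sample window has zero variance where variance is required."""


class UndefinedFeatureError(RFQUSError, ValueError):
    """A spectral feature is undefined (zero in-band power)."""


class DegenerateSpectrumError(RFQUSError, ValueError):
    """A time series is constant, so its normalized spectrum is undefined."""


class UndefinedDECError(RFQUSError, ValueError):
    """A direct-energy-coefficient ratio is undefined (zero segment energy)."""


class InvalidMapError(RFQUSError, ValueError):
    """A feature map contains non-finite values inside its valid region."""


class IncompleteCaseError(RFQUSError, ValueError):
    """A case is missing features required by the canonical feature table."""


class InvalidDesignError(RFQUSError, ValueError):
    """A label vector or CV design is degenerate (e.g. a single class)."""


class PartitionError(RFQUSError, ValueError):
    """A cross-validation fold ended up with a single class."""


class UndefinedROCError(RFQUSError, ValueError):
    """ROC analysis is undefined because only one class is present."""
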