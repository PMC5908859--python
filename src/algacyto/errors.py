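"""Exception hierarchy for the algacyto pipeline."""


class AlgacytoError(Exception):
    """Base class for all package-specific errors."""


class ChannelPairingError(AlgacytoError):
    """The two channels of a field do not match (shape, or missing partner file)."""


class FormatError(AlgacytoError):
    """Unsupported raster layout or dtype."""


class ConversionError(AlgacytoError):
    """Grayscale conversion mode incompatible with the raster shape."""


class DegenerateHistogramError(AlgacytoError):
    """Thresholding requested on an image with a single gray level."""


class ReadoutError(AlgacytoError):
    """Label mask and raw raster are incompatible."""


class DegenerateScaleError(AlgacytoError):
    """Relative scaling requested for a vector with non-positive mean."""


class GroupingError(AlgacytoError):
    """Cell records from different timepoints/conditions mixed into one snapshot."""


class UndefinedCorrelationError(AlgacytoError):
    """Rank correlation undefined (constant ranks or too few observations)."""


class PlacementError(AlgacytoError):
    """Non-overlapping cell placement failed within the retry budget."""


class ConfigurationError(AlgacytoError):
    """Invalid run configuration (no input pairs, bad parameters, ...)."""


class AnalysisError(AlgacytoError):
    """Population analysis cannot proceed (e.g. missing baseline timepoint)."""
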