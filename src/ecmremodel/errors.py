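"""Exception hierarchy for the remodeling-score pipeline.

Configuration problems (bad parameters, bad channel maps) and data problems
(degenerate images, empty masks) are kept distinct so the CLI can map them
onto different exit codes.
"""


class EcmError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EcmError):
    """Invalid configuration or parameter value."""


class ParameterError(ConfigError):
    """A numeric parameter is outside its legal range."""


class FormatError(EcmError):
    """An input file or channel map does not match the expected layout."""


class DimensionError(FormatError):
    """Image planes or channels disagree in shape."""


class DataError(EcmError):
    """The data are valid in format but degenerate for the analysis."""


class GeometryError(DataError):
    """Simulated geometry (e.g. a cell cluster) does not fit the field."""


class NoMatrixError(DataError):
    """No plane reaches the minimum stain-positive coverage for layering."""


class EmptyMaskError(DataError):
    """A region mask required for scoring is empty (e.g. no nuclei found)."""


class TransformError(DataError):
    """A value transform (e.g. log) received out-of-domain data."""


class DegenerateVarianceError(DataError):
    """Within-group variance is zero; the F statistic is undefined."""


class MissingControlError(DataError):
    """The untreated control group required for comparison is absent."""
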