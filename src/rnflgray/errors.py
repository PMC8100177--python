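"""Exception hierarchy.

Errors are split so callers can distinguish *invalid use* (bad arguments,
bad configuration) from *data-driven failure* (an image the segmenter
cannot handle), which is an expected outcome on poor scans and feeds the
pipeline's exclusion accounting rather than aborting a run.
"""


class RnflGrayError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RnflGrayError):
    """Invalid generative or pipeline configuration (e.g. a negative
    residual-variance budget)."""


class GeometryError(RnflGrayError):
    """Rendered layer geometry does not fit the requested image frame."""


class SegmentationFailure(RnflGrayError):
    """No admissible boundary path was found; distinct from QC flagging,
    which returns a report instead of raising."""


class MeasurementError(RnflGrayError):
    """A quantification request over an empty pixel band."""


class QCRefusalError(RnflGrayError):
    """Measurement requested on a scan whose QC report flags boundary
    misidentification and the caller did not override."""


class SchemaError(RnflGrayError):
    """A cohort CSV is missing a mandatory column."""


class NotEstimableError(RnflGrayError):
    """A statistic cannot be computed from the given data (constant
    covariate, too few observations, zero variance)."""
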