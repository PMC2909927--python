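"""Exception hierarchy for the pipeline.

All pipeline-specific failures derive from :class:`IrisPipeError` so callers can
catch the whole family; ``InvalidArgumentError`` additionally derives from
``ValueError`` for idiomatic use.
"""


class IrisPipeError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgumentError(IrisPipeError, ValueError):
    """An argument violated a documented precondition."""


class DegenerateInputError(IrisPipeError):
    """The input carries no usable signal (e.g. a constant image has no edges)."""


class EstimateFailureError(IrisPipeError):
    """The coarse pupil estimate (thresholding + blob analysis) found no candidate."""


class SegmentationFailureError(IrisPipeError):
    """A full segmentation attempt failed; ``stage`` names the stage that failed."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(message or f"segmentation failed at stage {stage!r}")


class UndefinedComparisonError(IrisPipeError):
    """Two codes share no valid bits, so their Hamming distance is undefined."""
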