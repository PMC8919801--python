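"""Typed exceptions raised across the pipeline.

Every stage failure carries a named error so callers (and the pipeline
orchestrator) can distinguish bad inputs from bugs.
"""


class FingertapError(Exception):
    """Base class for all package errors."""


class ParameterError(FingertapError, ValueError):
    """An invalid generator or model parameter; names the offending field."""


class InsufficientDataError(FingertapError, ValueError):
    """A series or event sequence is too short for the requested operation."""


class DegenerateSignalError(FingertapError, ValueError):
    """A signal with no usable variation (e.g. constant distance)."""


class UnsupportedRateError(FingertapError, ValueError):
    """Sampling rate outside the supported {30, 60} Hz set."""


class TooFewEventsError(InsufficientDataError):
    """Fewer tap events than the feature families require."""


class FeatureExtractionError(FingertapError, RuntimeError):
    """A feature family failed; names the family and hand."""


class EmptyDatasetError(FingertapError, ValueError):
    """A cohort specification with zero recordings."""


class ValidationError(FingertapError, ValueError):
    """Clinical-score or input-schema validation failure."""
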