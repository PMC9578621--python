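"""Exception hierarchy for input validation and model preconditions."""


class FerticastError(Exception):
    """Base class for all package errors."""


class ValidationError(FerticastError):
    """Invalid data or parameters."""


class PeriodLabelError(ValidationError):
    """A period label is not a well-formed 5-year span 'YYYY-YYYY'."""


class TFRValueError(ValidationError):
    """A TFR value is missing, non-numeric or non-positive."""


class GridMismatchError(ValidationError):
    """Series in one panel do not share a single contiguous period grid."""


class ParameterRangeError(ValidationError):
    """A model parameter lies outside its admissible open range."""


class PhaseError(FerticastError):
    """A phase-detection or phase-assignment precondition failed."""


class ModelError(FerticastError):
    """A model-fitting precondition failed (identifiability, sample size...)."""
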