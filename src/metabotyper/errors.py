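"""Exception hierarchy shared across the pipeline."""


class MetabotyperError(Exception):
    """Base class for all package errors."""


class ValidationError(MetabotyperError, ValueError):
    """Invalid configuration, spec, or input-table contents."""


class SchemaError(ValidationError):
    """A table is missing required columns or has malformed values."""


class InvalidAssayError(MetabotyperError, ValueError):
    """A calibration fit is unusable (non-positive slope, degenerate design)."""


class MissingValueError(MetabotyperError, ValueError):
    """Every replicate of a measurement cell was excluded."""


class UndefinedStatisticError(MetabotyperError, ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
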