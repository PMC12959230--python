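"""Exception hierarchy shared across the pipeline."""


class SepalvarError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(SepalvarError, ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(SepalvarError, ValueError):
    """A data object (contour, mask, table ...) is degenerate or malformed."""


class InsufficientDataError(SepalvarError, ValueError):
    """Fewer observations than the statistic requires."""


class UndefinedCorrelationError(SepalvarError, ValueError):
    """Pearson correlation undefined (zero variance in one variable)."""


class SchemaError(SepalvarError, ValueError):
    """A file does not match the documented column schema."""
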