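"""Exception hierarchy shared across the package."""


class SleepTransferError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SleepTransferError):
    """A required column or field is missing or malformed."""


class FeatureParseError(SleepTransferError):
    """A feature cell could not be parsed as a finite number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ShapeMismatchError(SleepTransferError):
    """Two inputs that must share a dimension do not."""


class InsufficientDataError(SleepTransferError):
    """Too few samples for the requested computation."""


class DegenerateDataError(SleepTransferError):
    """Input is degenerate (zero spread, identical points, single class...)."""


class ParameterError(SleepTransferError):
    """A parameter is outside its valid range."""


class UsageError(SleepTransferError):
    """An object was used in a way its kind does not support."""


class ConfigError(SleepTransferError):
    """A configuration is inconsistent or infeasible."""
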