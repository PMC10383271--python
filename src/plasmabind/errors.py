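"""Exception hierarchy shared across the package."""


class PlasmaBindError(Exception):
    """Base class for all package errors."""


class ValidationError(PlasmaBindError, ValueError):
    """Input violates a documented precondition or invariant."""


class ConfigurationError(PlasmaBindError):
    """A configuration, registry, or ground-truth object is inconsistent."""


class InsufficientDataError(PlasmaBindError, ValueError):
    """Too few usable data points for the requested fit."""


class FormulaParseError(ValidationError):
    """Molecular formula string could not be tokenized.

    ``position`` is the 0-based index in the input string where
    tokenization failed.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class UnsupportedElementError(FormulaParseError):
    """Formula contains an element outside the supported isotope table."""

    def __init__(self, symbol: str, position: int | None = None):
        super().__init__(f"unsupported element {symbol!r}", position)
        self.symbol = symbol


class MissingDescriptorError(ValidationError):
    """A rule evaluation requires a descriptor that was not supplied."""

    def __init__(self, descriptor: str):
        super().__init__(f"missing descriptor {descriptor!r}")
        self.descriptor = descriptor


class ConditioningError(PlasmaBindError, ValueError):
    """A basis or design matrix is too ill-conditioned to invert reliably."""
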