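"""Exception hierarchy shared across the package."""


class M6ABindError(Exception):
    """Base class for all package errors."""


class ValidationError(M6ABindError, ValueError):
    """Raised when inputs violate a documented precondition."""


class FittingError(M6ABindError, RuntimeError):
    """Raised when a least-squares fit fails or is underdetermined.

    Carries optional diagnostics (residuals, starting values) to help
    diagnose pathological traces.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class BedParseError(M6ABindError, ValueError):
    """Raised on malformed BED input; records the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class GenerationError(M6ABindError, RuntimeError):
    """Raised when a synthetic-data generator cannot satisfy its constraints."""
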