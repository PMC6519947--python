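"""Exception hierarchy shared across the package.

Validation errors signal bad inputs or violated physical invariants (CLI exit
code 2); numerical errors signal a solver failure (exit code 3).
"""


class DepotSimError(Exception):
    """Base class for all package errors."""


class ValidationError(DepotSimError, ValueError):
    """Invalid input: bad parameter value, violated invariant, malformed file."""


class ParseError(ValidationError):
    """A file could not be parsed; carries the offending line number if known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class AlignmentError(ValidationError):
    """Two series that must share a sampling grid do not."""


class ExtrapolationError(ValidationError):
    """A lookup was requested outside the tabulated range."""


class InsufficientPointsError(ValidationError):
    """A statistic was requested on too few points."""


class NumericalError(DepotSimError, RuntimeError):
    """The linear solve or time integration failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
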