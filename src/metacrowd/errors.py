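"""Exception hierarchy shared across the package."""


class MetacrowdError(Exception):
    """Base class for all package errors."""


class ConfigError(MetacrowdError):
    """A configuration problem: missing column mapping, bad dialect, bad path."""


class ValidationError(MetacrowdError):
    """Input data violates a documented precondition or invariant."""


class RowError(ValidationError):
    """A row-level parse or range failure; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
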