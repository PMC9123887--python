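"""Exception hierarchy used across the pipeline."""


class WhistlegamError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(WhistlegamError):
    """An input table is missing required columns or has the wrong dtypes."""


class RowError(WhistlegamError):
    """A specific input row is invalid; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line is not None else ""))


class ValidationError(WhistlegamError):
    """Data violates a documented invariant (e.g. event outside its deployment)."""


class ConfigError(WhistlegamError):
    """A configuration value is inconsistent or incomplete."""


class CoverageError(WhistlegamError):
    """A covariate source series does not cover the requested time span."""

    def __init__(self, message: str, missing_span=None):
        self.missing_span = missing_span
        super().__init__(message)


class FitError(WhistlegamError):
    """Model fitting failed; carries the iteration trace when available."""

    def __init__(self, message: str, trace=None):
        self.trace = trace
        super().__init__(message)
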