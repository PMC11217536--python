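"""Exception hierarchy shared across the package."""


class MRScreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MRScreenError):
    """A required column is missing from an input table."""


class ValidationError(MRScreenError):
    """A value in an input table violates a field invariant.

    ``row`` is the 1-based data-row number (header excluded) when known.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class InputError(MRScreenError):
    """Structurally invalid input (e.g. duplicate variant ids)."""


class ConfigError(MRScreenError):
    """Inconsistent configuration values."""


class DegenerateInstrumentError(MRScreenError):
    """An instrument with a zero exposure effect cannot form a Wald ratio."""


class DegenerateFrequencyError(MRScreenError):
    """Effect-allele frequency of exactly 0 or 1 leaves no variance to explain."""


class SampleSizeError(MRScreenError):
    """Sample size too small for the requested F-statistic denominator."""


class InsufficientInstrumentsError(MRScreenError):
    """Fewer instruments than the estimator's minimum."""


class ConvergenceError(MRScreenError):
    """Numerical optimization failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class DegenerateCorrectionError(MRScreenError):
    """Outlier correction removed every instrument."""
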