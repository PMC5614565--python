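"""Exception hierarchy shared across the package."""


class WrcbindError(Exception):
    """Base class for all package-specific errors."""


class ParameterDomainError(WrcbindError, ValueError):
    """A physical parameter is outside its admissible domain (e.g. K_D <= 0)."""


class UndefinedObservableError(WrcbindError, ValueError):
    """An observable is requested for a state in which it is undefined."""


class InsufficientDataError(WrcbindError, ValueError):
    """Too few data points to support the requested fit."""


class NonConvergenceError(WrcbindError, RuntimeError):
    """All optimization starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class ComparisonDomainError(WrcbindError, ValueError):
    """Model comparison requested between fits that are not comparable."""


class UnsaturatedTraceError(WrcbindError, ValueError):
    """A fluorescence trace never reaches a plateau and no plateau was supplied."""


class DecompositionError(WrcbindError, ValueError):
    """The spectral decomposition system is ill-conditioned."""


class UndefinedRatioError(WrcbindError, ValueError):
    """A molar ratio is requested over a range with no receptor signal."""


class ConfigError(WrcbindError, ValueError):
    """A run configuration failed validation; carries offending field paths."""

    def __init__(self, message: str, fields=None):
        super().__init__(message)
        self.fields = list(fields or [])


class CsvFormatError(WrcbindError, ValueError):
    """A CSV input does not match the documented dialect."""
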