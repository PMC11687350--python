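"""Exception types shared across the package."""


class PolydemError(Exception):
    """Base class for package errors."""


class SchemaError(PolydemError):
    """A table is missing mandatory columns or violates structural rules."""

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class FitError(PolydemError):
    """A regression failed (separation, singular design, non-convergence).

    Carries the candidate term set so callers can report which model broke.
    """

    def __init__(self, message: str, terms=()):
        super().__init__(message)
        self.terms = tuple(terms)


class AICcUndefinedError(PolydemError):
    """AICc small-sample correction has a pole at n = k + 1."""


class KernelError(PolydemError):
    """Kernel assembly or eigenanalysis failed; names the offending piece."""


class ExtinctionError(PolydemError):
    """The simulated lineage went extinct before a growth rate was estimable."""

    def __init__(self, message: str, year: int | None = None):
        super().__init__(message)
        self.year = year


class ConfigError(PolydemError):
    """Invalid run configuration."""
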