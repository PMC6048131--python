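"""Exception hierarchy used across the package."""


class DomfitError(Exception):
    """Base class for all package-specific errors."""


class InvalidStateError(DomfitError):
    """An operation was called on an object in the wrong state
    (e.g. folding an already-folded spectrum, querying an empty grid)."""


class SpectrumParseError(DomfitError):
    """A .fs file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NumericalFailureError(DomfitError):
    """A numerical solve did not converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class OptimizationFailureError(DomfitError):
    """No optimizer start converged; carries the best incumbent found."""

    def __init__(self, message: str, incumbent=None):
        self.incumbent = incumbent
        super().__init__(message)


class ResourceLimitError(DomfitError):
    """A brute-force computation was requested at an infeasible size."""
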