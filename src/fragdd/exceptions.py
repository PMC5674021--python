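"""Exception hierarchy for the fragdd pipeline.

All errors raised by the library derive from :class:`FragddError` so callers
can catch pipeline failures without intercepting programming errors.
"""


class FragddError(Exception):
    """Base class for all fragdd errors."""


class FormatError(FragddError, ValueError):
    """An input file does not have the expected columns or structure."""


class ValidationError(FragddError, ValueError):
    """A value violates a contract (negative count, Q outside [0, 1], ...)."""


class SchemaError(FragddError, ValueError):
    """Inconsistent class-label schemes across counties of one landscape."""


class DataError(FragddError, ValueError):
    """Too few or degenerate observations for the requested operation."""


class FitError(FragddError, RuntimeError):
    """A nonlinear fit failed to converge after bounded restarts."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual
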