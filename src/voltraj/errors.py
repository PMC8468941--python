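"""Exception hierarchy shared across the package."""


class VoltrajError(Exception):
    """Base class for all package errors."""


class SchemaError(VoltrajError):
    """An input table is missing required columns or has an invalid layout."""


class RowParseError(VoltrajError):
    """A data row could not be parsed; carries the zero-based row index."""

    def __init__(self, row_index: int, message: str):
        super().__init__(f"row {row_index}: {message}")
        self.row_index = row_index


class EmptyInputError(VoltrajError):
    """An input that must contain data is empty."""


class UnitError(VoltrajError):
    """Unknown measurement unit label."""


class DomainError(VoltrajError):
    """A numeric argument is outside its valid domain."""


class InsufficientDataError(VoltrajError):
    """Too few observations for the requested fit (non-positive df)."""


class ConvergenceError(VoltrajError):
    """No optimizer start converged; carries diagnostics of the best attempt."""

    def __init__(self, message: str, best_sse: float | None = None):
        super().__init__(message)
        self.best_sse = best_sse


class NonIdentifiabilityError(VoltrajError):
    """Singular or numerically rank-deficient normal equations at the optimum."""


class StateError(VoltrajError):
    """An object is not in the state an operation requires (e.g. unconverged fit)."""


class PropagationError(VoltrajError):
    """Monte-Carlo propagation failed (e.g. excessive bound rejections)."""


class ExtrapolationError(VoltrajError):
    """A query age lies outside the band's age grid."""


class DegenerateBandError(VoltrajError):
    """Band has zero predictive variance; a z-score is undefined."""


class GenerationError(VoltrajError):
    """The synthetic generator produced an invalid draw under the given config."""
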