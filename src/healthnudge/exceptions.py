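"""Exception hierarchy shared across the package."""


class HealthNudgeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(HealthNudgeError, ValueError):
    """An input violates a documented precondition."""


class InvalidParameterError(HealthNudgeError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateInputError(InvalidInputError):
    """Input is structurally valid but statistically degenerate (e.g. zero variance)."""


class EstimationError(HealthNudgeError, RuntimeError):
    """A model fit could not be completed (rank deficiency, separation, non-convergence)."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnreachableTargetError(HealthNudgeError, RuntimeError):
    """An image-transform search could not reach the requested attractiveness delta.

    Carries the best delta that *was* achieved so callers can fall back to it.
    """

    def __init__(self, message: str, best_delta: float, best_gains: tuple | None = None):
        super().__init__(message)
        self.best_delta = best_delta
        self.best_gains = best_gains


class GenerationError(HealthNudgeError, RuntimeError):
    """A synthetic-data generator could not satisfy its constraints."""


class SchemaError(HealthNudgeError, ValueError):
    """A data file does not match the declared column contract."""
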