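"""Exception types shared across the pipeline."""


class InvalidParameterError(ValueError):
    """A parameter value is outside its documented domain."""


class InvalidInputError(ValueError):
    """An input array/table violates a precondition (shape, emptiness, ...)."""


class CoRegistrationError(ValueError):
    """Two rasters that must share a grid do not."""


class SamplingError(ValueError):
    """A sample request cannot be satisfied by the available pixels."""


class ConfigurationError(ValueError):
    """A config object is internally inconsistent or infeasible."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge within its budget."""

    def __init__(self, message: str, class_id: int | None = None,
                 gradient_norm: float | None = None):
        super().__init__(message)
        self.class_id = class_id
        self.gradient_norm = gradient_norm


class DegenerateProbabilityError(RuntimeError):
    """All class weights vanished for at least one prediction row."""
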