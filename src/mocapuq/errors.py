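"""Exception hierarchy for mocapuq."""


class MocapUQError(Exception):
    """Base class for all mocapuq errors."""


class ModelError(MocapUQError):
    """Invalid model definition (bad tree, duplicate names, bad inertia...)."""


class DomainError(MocapUQError):
    """Input outside the documented domain of an operation."""


class UnderdeterminedError(DomainError):
    """Too few usable markers to pose the model."""


class ConvergenceError(MocapUQError):
    """Iterative solver exhausted its iteration budget."""

    def __init__(self, message: str, final_residual: float | None = None):
        super().__init__(message)
        self.final_residual = final_residual


class RejectionCapError(MocapUQError):
    """Rejection sampler exceeded its draw budget without an acceptance."""


class ParseError(MocapUQError):
    """Malformed input file."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
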