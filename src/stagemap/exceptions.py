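"""Exception hierarchy for stagemap."""


class StagemapError(Exception):
    """Base class for all package errors."""


class InvalidInputError(StagemapError, ValueError):
    """Malformed or inconsistent user input (shapes, labels, non-finite values)."""


class ParameterDomainError(StagemapError, ValueError):
    """A hyperparameter outside its admissible domain."""


class DegenerateInputError(InvalidInputError):
    """Input that is formally valid but information-free (e.g. all points identical)."""


class NumericalError(StagemapError, RuntimeError):
    """A numerical operation (factorization, solve) failed beyond recovery."""


class OptimizerStallError(StagemapError, RuntimeError):
    """The optimizer could not make progress; carries the best iterate found."""

    def __init__(self, message: str, best_x=None, best_f=None, trace=None):
        super().__init__(message)
        self.best_x = best_x
        self.best_f = best_f
        self.trace = trace


class UnsupportedKernelError(StagemapError, ValueError):
    """Operation not defined for the requested kernel configuration."""


class UnsupportedDimensionError(StagemapError, ValueError):
    """Operation defined only for a specific latent dimensionality."""
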