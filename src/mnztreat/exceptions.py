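"""Exception hierarchy shared across the package."""


class MnZnTreatError(Exception):
    """Base class for all package errors."""


class SchemaError(MnZnTreatError, ValueError):
    """An input file does not match the documented schema."""


class ValidationError(MnZnTreatError, ValueError):
    """A record or value violates a domain invariant."""


class InsufficientDataError(MnZnTreatError, ValueError):
    """Not enough observations to compute the requested quantity."""


class DegenerateInputError(MnZnTreatError, ValueError):
    """Input is degenerate for the requested statistic (zero range/variance)."""


class NumericalError(MnZnTreatError, RuntimeError):
    """The integrator produced a non-finite state."""


class ConvergenceError(MnZnTreatError, RuntimeError):
    """Optimiser failed to converge; carries the best result so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class InfeasibleError(MnZnTreatError, ValueError):
    """No HRT in the search bracket satisfies the effluent limit."""
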