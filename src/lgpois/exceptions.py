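"""Exception hierarchy for lgpois."""


class LgpoisError(Exception):
    """Base class for all lgpois errors."""


class InvalidInputError(LgpoisError, ValueError):
    """Raised when input data violates a documented precondition."""


class ValidationError(InvalidInputError):
    """Raised by dataset readers when a column or row fails validation."""


class ConvergenceError(LgpoisError, RuntimeError):
    """Raised when an iterative fit fails to converge.

    Carries the last iterate so callers can inspect where the
    optimization stalled.
    """

    def __init__(self, message, last_iterate=None, n_iter=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.n_iter = n_iter


class DivergenceError(ConvergenceError):
    """Raised when coefficient estimates run away without bound.

    This is the observable form of the Poisson identification failure:
    with small samples and many zero counts the likelihood can be
    maximized only in the limit of infinite coefficients.
    """
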