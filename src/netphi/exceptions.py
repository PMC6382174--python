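"""Exception hierarchy shared across netphi modules."""


class NetphiError(Exception):
    """Base class for all netphi errors."""


class InvalidArgumentError(NetphiError, ValueError):
    """An argument violates an operation's preconditions."""


class DegenerateDataError(NetphiError, ValueError):
    """Input data are degenerate (e.g. a channel with zero variance)."""


class ConditioningError(NetphiError, ValueError):
    """A matrix is too ill-conditioned for a stable solve.

    Carries the offending condition number in ``condition_number``.
    """

    def __init__(self, message: str, condition_number: float | None = None):
        super().__init__(message)
        self.condition_number = condition_number


class NotPositiveDefiniteError(NetphiError, ValueError):
    """A covariance matrix required to be positive definite is not."""


class DegenerateGraphError(NetphiError, ValueError):
    """A graph is unusable for the requested operation (e.g. all-zero weights)."""


class GenerationFailureError(NetphiError, RuntimeError):
    """A random generator exhausted its retry budget."""


class DivergenceError(NetphiError, RuntimeError):
    """A numerical integration blew up."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step
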