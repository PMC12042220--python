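"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class ConvergenceError(RuntimeError):
    """The iterative least-squares solver stopped before reaching tolerance.

    Attributes
    ----------
    residual : float
        Relative residual at the point the solver gave up.
    iterations : int
        Number of iterations performed.
    """

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations
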