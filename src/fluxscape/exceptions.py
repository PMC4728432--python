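"""Exception hierarchy."""


class FluxscapeError(Exception):
    """Base class for all package errors."""


class ParseError(FluxscapeError):
    """Malformed model file, GPR string, or input table."""


class ValidationError(FluxscapeError):
    """Input violates a documented precondition or invariant."""


class InfeasibleError(FluxscapeError):
    """The constraint system admits no flux distribution."""


class SolverError(FluxscapeError):
    """LP/MILP solver failed or hit its time limit."""

    def __init__(self, message: str, best_bound: float | None = None):
        super().__init__(message)
        self.best_bound = best_bound
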