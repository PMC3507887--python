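"""Exception hierarchy.

Validation problems (bad configuration, malformed input tables) raise
:class:`ValidationError`; numerical failures (non-convergent fits, degenerate
likelihoods) raise :class:`NumericalError`.  The CLI maps these to exit codes
2 and 3 respectively.
"""


class TwoTissueError(Exception):
    """Base class for all package errors."""


class ValidationError(TwoTissueError):
    """Invalid configuration or malformed input data."""


class NumericalError(TwoTissueError):
    """A numerical procedure failed (non-convergence, degenerate model)."""


class ConvergenceError(NumericalError):
    """Optimizer did not converge; carries the best point found."""

    def __init__(self, message, best_params=None, grad_norm=None):
        super().__init__(message)
        self.best_params = best_params
        self.grad_norm = grad_norm


class DegeneratePriorError(NumericalError):
    """Variance-prior likelihood is unbounded (zero dispersion in s^2)."""
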