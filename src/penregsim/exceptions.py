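"""Exception hierarchy for penregsim."""


class PenregsimError(Exception):
    """Base class for all penregsim errors."""


class InvalidCorrelationError(PenregsimError, ValueError):
    """Matrix is not a valid (symmetric, unit-diagonal, positive-definite) correlation matrix."""


class CalibrationError(PenregsimError, RuntimeError):
    """VIF calibration failed to reach the requested tolerance.

    Carries the best achieved VIF vector in ``achieved_vifs``.
    """

    def __init__(self, message, achieved_vifs=None):
        super().__init__(message)
        self.achieved_vifs = achieved_vifs


class InvalidPenaltyError(PenregsimError, ValueError):
    """Negative or otherwise invalid penalty weights."""


class ConvergenceError(PenregsimError, RuntimeError):
    """Coordinate descent failed to converge within the iteration cap."""

    def __init__(self, message, gap=None):
        super().__init__(message)
        self.gap = gap


class SingularDesignError(PenregsimError, ValueError):
    """Design matrix (with intercept column) is rank deficient."""


class DegenerateFitError(PenregsimError, ValueError):
    """Residual sum of squares is zero or negative; information criteria undefined."""


class FoldSizeError(PenregsimError, ValueError):
    """A cross-validation fold has fewer than two observations."""


class DegreesOfFreedomError(PenregsimError, ValueError):
    """Sample size too small for the number of parameters."""
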