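"""Exception types shared across the package."""


class GeometryError(ValueError):
    """A structure, window, or profile endpoint violates geometric constraints."""


class ConfigurationError(ValueError):
    """A requested configuration admits no valid realization."""


class InfeasibleAFError(ValueError):
    """The sampling budget round(N^2/AF) cannot cover the calibration disk.

    Carries ``max_feasible_af``, the largest acceleration factor for which the
    fully sampled center disk still fits in the budget.
    """

    def __init__(self, message: str, max_feasible_af: float):
        super().__init__(message)
        self.max_feasible_af = max_feasible_af


class DegenerateInputError(ValueError):
    """An input is degenerate for the requested statistic (e.g. zero noise)."""


class NumericalError(RuntimeError):
    """An iterative solver diverged or produced non-finite values."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class ContractError(ValueError):
    """Objects from different pipeline runs were combined inconsistently."""
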