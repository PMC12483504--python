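"""Exception hierarchy shared across the package."""


class NrevError(Exception):
    """Base class for all package-specific errors."""


class DomainError(NrevError, ValueError):
    """An argument is outside its mathematical domain."""


class DegenerateGeneratorError(DomainError):
    """A rate matrix row has no positive off-diagonal entry (absorbing state)."""


class ReducibleGeneratorError(NrevError):
    """The generator has no unique stationary distribution."""


class LabellingError(NrevError, KeyError):
    """Tip labels of a tree and the sequence names of an alignment disagree."""


class FormatError(NrevError, ValueError):
    """A file does not conform to the expected format."""


class ConvergenceError(NrevError, RuntimeError):
    """Numerical optimization failed to converge; carries the best fit so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class CalibrationError(NrevError, RuntimeError):
    """A calibration target (e.g. average pairwise identity) is unreachable."""
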