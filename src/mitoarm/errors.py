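"""Exception hierarchy shared across the package."""


class MitoarmError(Exception):
    """Base class for all package-specific errors."""


class GnetParseError(MitoarmError, ValueError):
    """A graph file could not be parsed; the message names the offending line."""


class ValidationError(MitoarmError, ValueError):
    """An input violated a documented precondition or invariant."""


class UndefinedMetricError(MitoarmError, ArithmeticError):
    """A metric is mathematically undefined for this input (e.g. zero length)."""


class NoTransitionError(MitoarmError, ValueError):
    """A melt curve shows no unfolding transition inside the scanned range."""


class FitError(MitoarmError, RuntimeError):
    """A nonlinear fit failed to converge; diagnostics are in the message."""
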