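"""Exception hierarchy for nesbr3.

All signalling is via exceptions (or explicit flags on result objects), never
silent NaNs: a quantity that does not exist raises :class:`DivergentMomentError`,
a hazard evaluated where the survival function has underflowed raises
:class:`HazardOverflowError`, and so on.
"""


class NesBr3Error(Exception):
    """Base class for all package errors."""


class DomainError(NesBr3Error, ValueError):
    """Argument outside the mathematical domain (e.g. x <= 0, q not in (0,1))."""


class ParameterError(NesBr3Error, ValueError):
    """Invalid distribution parameters (non-positive shapes, bad indeterminacy)."""


class DataError(NesBr3Error, ValueError):
    """Invalid sample data (non-positive observations, inverted intervals)."""


class ParseError(DataError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DivergentMomentError(NesBr3Error, ArithmeticError):
    """The requested moment (or entropy integral) does not exist."""


class HazardOverflowError(NesBr3Error, FloatingPointError):
    """Hazard rate requested where the survival function is zero to machine precision."""


class ConvergenceError(NesBr3Error, RuntimeError):
    """Optimizer failed to converge after all starts; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class UndefinedCriterionError(NesBr3Error, ValueError):
    """An information criterion is undefined for the given (n, k)."""
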