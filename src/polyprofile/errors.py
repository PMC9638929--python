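"""Exception hierarchy.

All package errors derive from :class:`PolyProfileError` so callers can
catch everything with one clause; data-shaped problems additionally derive
from :class:`ValueError` and numerical failures from :class:`RuntimeError`.
"""


class PolyProfileError(Exception):
    """Base class for all errors raised by polyprofile."""


class InvalidInputError(PolyProfileError, ValueError):
    """Input data violate a documented precondition."""


class InsufficientDataError(InvalidInputError):
    """Too few observations to perform the requested fit."""


class DegenerateInputError(InvalidInputError):
    """Input is formally valid but carries no usable signal (e.g. all-zero counts)."""


class DegenerateProfileError(InvalidInputError):
    """A fitted profile has zero total peak mass; volumes are undefined."""


class DegenerateNullError(InvalidInputError):
    """Pairwise RMSDs have zero variance; no normal null can be fitted."""


class UndefinedRatioError(InvalidInputError):
    """P/M ratio requested but the monosome volume is zero."""


class DomainError(InvalidInputError):
    """A peak index outside the domain of the location model (index <= 0)."""


class FitFailureError(PolyProfileError, RuntimeError):
    """Nonlinear least squares failed to converge.

    Carries the last root-mean-square residual in :attr:`last_residual`.
    """

    def __init__(self, message: str, last_residual: float | None = None):
        super().__init__(message)
        self.last_residual = last_residual
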