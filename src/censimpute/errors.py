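"""Exception hierarchy.

All package errors derive from :class:`CensImputeError` so callers can catch
one type; each also derives from the closest builtin (ValueError/RuntimeError)
so unaware code still sees a conventional category.
"""


class CensImputeError(Exception):
    """Base class for all errors raised by censimpute."""


class InsufficientDataError(CensImputeError, ValueError):
    """Too few records/replicates to perform the requested computation."""


class DomainError(CensImputeError, ValueError):
    """An input value lies outside the mathematically valid domain."""


class ConfigurationError(CensImputeError, ValueError):
    """Inconsistent configuration, e.g. a lower cutoff at or above the upper."""


class CalibrationError(CensImputeError, RuntimeError):
    """The calibration fit produced an unusable curve (nonpositive slope)."""


class NoOperationalRangeError(CensImputeError, ValueError):
    """No concentration on the measurement range meets the CV acceptance cutoff."""


class MissingRangeError(CensImputeError, ValueError):
    """An imputation method needs a finite measurement-range bound that is unset."""


class EmptyIntervalError(CensImputeError, ValueError):
    """A truncation interval carries zero probability mass."""


class FitError(CensImputeError, RuntimeError):
    """Maximum-likelihood fitting failed irrecoverably."""


class ValidationError(CensImputeError, ValueError):
    """A data file violated the expected format or value constraints."""
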