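"""Exception hierarchy.

Every error raised by the package derives from :class:`WisdomError`, so
callers can catch one base class. Validation errors (bad shapes, bad
labels, bad configuration) derive from :class:`ValidationError`;
numerical failures (singular or indefinite matrices) from
:class:`NumericalError`. The split mirrors the CLI exit codes
(2 = validation, 3 = numerical).
"""


class WisdomError(Exception):
    """Base class for all package errors."""


class ValidationError(WisdomError):
    """Invalid input shapes, labels, or configuration."""


class NumericalError(WisdomError):
    """A matrix factorization or density evaluation failed."""


# --- matrix validity -------------------------------------------------------

class NonSquareError(ValidationError):
    pass


class AsymmetricError(NumericalError):
    pass


class NotPositiveDefiniteError(NumericalError):
    pass


class SingularScaleError(NumericalError):
    pass


class DomainError(ValidationError):
    """Argument outside the mathematical domain (e.g. gamma of a non-positive number)."""


# --- dimensions and degrees of freedom ------------------------------------

class DimensionMismatchError(ValidationError):
    pass


class DegreesOfFreedomError(ValidationError):
    """Degrees of freedom below the matrix dimension (p > n regime)."""


# --- class models ----------------------------------------------------------

class EmptyClassError(ValidationError):
    pass


class UnlabeledElementError(ValidationError):
    pass


class ClassTooSmallError(ValidationError):
    pass


class MoreThanTwoClassesError(ValidationError):
    pass


# --- scoring ----------------------------------------------------------------

class EmptyResultError(ValidationError):
    """Deleting every feature would leave an empty matrix."""


class EmptyTableError(ValidationError):
    pass


# --- time series -------------------------------------------------------------

class LengthMismatchError(ValidationError):
    pass


class BatchTooShortError(ValidationError):
    pass


class DegenerateChannelError(NumericalError):
    """A channel with zero variance cannot enter a correlation matrix."""


# --- synthetic / pipeline ----------------------------------------------------

class SpecError(ValidationError):
    pass


class SizeTooLargeError(ValidationError):
    pass
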