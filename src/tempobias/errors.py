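"""Exception hierarchy shared across the package."""


class TempoBiasError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(TempoBiasError, ValueError):
    """An argument violated a documented precondition."""


class GenerationFailureError(TempoBiasError, RuntimeError):
    """Constrained randomization failed within the attempt budget."""


class DegenerateFitError(TempoBiasError, ValueError):
    """A regression design was rank deficient (e.g., a single tempo)."""


class UndefinedShiftError(TempoBiasError, ZeroDivisionError):
    """Shift statistic undefined because the calibration slope is zero."""


class SingularCovarianceError(TempoBiasError, ValueError):
    """A covariance matrix required by a multivariate test was singular."""


class MissingSliceError(TempoBiasError, ValueError):
    """A condition slice lost a pitch level or is empty."""


class SchemaError(TempoBiasError, ValueError):
    """An input table is missing required columns."""


class ValidationError(TempoBiasError, ValueError):
    """An input table contains out-of-range or malformed values."""
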