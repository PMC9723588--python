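"""Exception hierarchy.

Every error raised on a violated precondition is a subclass of
:class:`LakeBrowningError`, itself a ``ValueError`` so that callers who do not
care about the fine-grained type can catch the standard built-in.
"""


class LakeBrowningError(ValueError):
    """Base class for all package-specific errors."""


class InvalidDesignError(LakeBrowningError):
    """Gradient or regime design violates its invariants."""


class InvalidMixError(LakeBrowningError):
    """Shape-mix proportions are negative or do not sum to one."""


class DegenerateProfileError(LakeBrowningError):
    """A site's total expected abundance is zero."""


class InvalidProfileError(LakeBrowningError):
    """Probability profile contains negative entries."""


class ZeroRowError(LakeBrowningError):
    """A count row is all zero where a positive total is required."""


class UndefinedDistanceError(LakeBrowningError):
    """Bray-Curtis is undefined because both rows are all zero."""


class NoSolutionError(LakeBrowningError):
    """Fisher's alpha has no solution for the given (S, N)."""


class EstimatorUndefinedError(LakeBrowningError):
    """ACE sample coverage is zero (all rare taxa are singletons)."""


class InvalidDepthError(LakeBrowningError):
    """Rarefaction depth exceeds the available number of reads."""


class DegenerateColumnError(LakeBrowningError):
    """A constant column cannot be standardized."""


class InvalidPartitionError(LakeBrowningError):
    """A MINE axis partition has fewer than two bins."""


class DegenerateVariableError(LakeBrowningError):
    """MINE statistics are undefined for a constant variable."""


class InvalidPError(LakeBrowningError):
    """A p-value lies outside (0, 1]."""


class InvalidHyperparameterError(LakeBrowningError):
    """A model hyperparameter is outside its valid range."""


class DivergenceError(LakeBrowningError):
    """Neural-network training produced a non-finite loss."""


class SplitError(LakeBrowningError):
    """Too few rows to split into train and test sets."""


class DegenerateGradientError(LakeBrowningError):
    """All gradient values are identical; no meshgrid axis exists."""


class ZeroVarianceError(LakeBrowningError):
    """R^2 is undefined because the evaluated targets have zero variance.

    Carries the mean-squared error that *is* defined in ``mse``.
    """

    def __init__(self, message: str, mse: float | None = None):
        super().__init__(message)
        self.mse = mse


class InvalidBandError(LakeBrowningError):
    """Turnover band width is incompatible with the surface axis."""


class CollinearityError(LakeBrowningError):
    """Predictor matrix is rank deficient."""


class DegenerateRegressionError(LakeBrowningError):
    """Regression on a constant predictor or response."""


class ConfigError(LakeBrowningError):
    """Pipeline configuration failed validation."""


class StageError(LakeBrowningError):
    """A pipeline stage failed; the stage name is in the message."""
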