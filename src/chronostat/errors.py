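"""Exception and warning types shared across the package."""


class ChronostatError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ChronostatError, ValueError):
    """A design or record field is out of its admissible range."""


class DegenerateDesignError(ChronostatError, ValueError):
    """Sampling design cannot identify the model (e.g. < 3 distinct ZTs)."""


class InsufficientDataError(ChronostatError, ValueError):
    """Too few records or matched cells for the requested statistic."""


class DegenerateTableError(ChronostatError, ValueError):
    """A contingency table with an expected count of zero."""


class NormalizationError(ChronostatError, ValueError):
    """Control reference is nonpositive, so percent-of-control is undefined."""


class UndefinedRatioError(ChronostatError, ValueError):
    """Denominator of a derived ratio is zero or nonpositive."""


class MissingDataError(ChronostatError, ValueError):
    """A required indicator or field is absent from a record."""


class PerfectFitWarning(UserWarning):
    """Residual sum of squares is numerically zero; p-value reported as 0."""


class UnbalancedDesignWarning(UserWarning):
    """Factorial design has empty or unequal cells."""


class IncompleteSectionWarning(UserWarning):
    """A tissue section contributed fewer images than expected."""


class EmptyStratumWarning(UserWarning):
    """A stratum implied by the observed factor levels has no records."""
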