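"""Exception hierarchy shared across the package."""


class DivadjError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DivadjError, ValueError):
    """Malformed input data (bad abundance, malformed file row, duplicate key)."""


class InsufficientDataError(DivadjError, ValueError):
    """The sample is too small for the requested estimator."""


class UndefinedEstimateError(DivadjError, ZeroDivisionError):
    """An estimator's denominator is empty (e.g. Good-Turing with f_r = 0)."""


class UnsupportedOrderError(DivadjError, ValueError):
    """Diversity order q outside the supported set for this operation."""


class UnreachableCoverageError(DivadjError, ValueError):
    """A target sample coverage exceeds the attainable limit."""
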