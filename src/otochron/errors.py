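"""Exception hierarchy.

Everything raised on purpose by this package derives from OtochronError so
callers can catch one type at pipeline level.
"""


class OtochronError(Exception):
    """Base class for all package errors."""


class ParameterError(OtochronError):
    """An argument is outside its documented domain."""


class DataError(OtochronError):
    """Input data violate a structural requirement (non-positive widths,
    degenerate age classes, non-contiguous ages, ...)."""


class CoverageError(OtochronError):
    """A covariate lookup (climate month, stock year/age) has no value for a
    key required by the data."""

    def __init__(self, message, missing=None):
        super().__init__(message)
        self.missing = list(missing) if missing is not None else []


class SpecificationError(OtochronError):
    """A model specification references unknown columns, is rank deficient,
    or asks for a component a fit does not contain."""


class ComparisonError(OtochronError):
    """Model comparison requested between incomparable fits."""


class AnalysisError(OtochronError):
    """A downstream analysis has too little usable data."""
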