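"""Exception hierarchy for the pipeline.

Domain errors on scalar kernels (negative masses, zero denominators) raise
plain :class:`ValueError`; structural problems with tabular inputs raise the
subclasses below so callers can distinguish bad data from bad arithmetic.
"""


class FoodGapError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FoodGapError):
    """A tabular input is missing required rows or columns."""


class UnitError(FoodGapError):
    """Unit unknown to the registry or dimensionally incompatible."""


class AlignmentError(FoodGapError):
    """Two inputs do not cover the same cohorts / age stages."""


class CoverageError(FoodGapError):
    """A time series does not cover a requested year window."""


class CalibrationError(FoodGapError):
    """Share-model calibration is impossible (no overlapping years)."""


class UndefinedGapError(FoodGapError):
    """Gap percentage requested where production is zero and demand positive."""
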