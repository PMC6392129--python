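"""Exception hierarchy.

Split by how the command-line layer maps failures to exit codes:
configuration problems (exit 2), data problems (exit 3), and statistical
non-identifiability (exit 4).
"""


class RatioampError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(RatioampError):
    """Invalid run configuration or panel definition."""


class DataError(RatioampError):
    """Invalid or inconsistent input data."""


class SchemaError(DataError):
    """A required column is missing from an input table."""


class CtParseError(DataError):
    """A Ct cell is neither a decimal number nor the token 'ND'."""


class UnknownAssayError(DataError):
    """A table references an assay_id absent from the panel."""


class MeltCurveError(DataError):
    """Every replicate of a (sample, assay) group failed melt-curve QC."""


class IncompleteSeriesError(DataError):
    """A degradation level lacks an aggregate for one assay of a pair."""


class InsufficientDataError(DataError):
    """Too few complete rows to compute a statistic."""


class DomainError(RatioampError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class NonIdentifiableError(RatioampError):
    """A fit has no unique solution (e.g. all predictor deltas are zero)."""
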