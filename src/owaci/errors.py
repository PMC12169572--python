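"""Exception hierarchy for validation and numerical degeneracies."""


class OwaciError(Exception):
    """Base class for all package errors."""


class ValidationError(OwaciError):
    """Input data or configuration violates a documented contract."""


class DegenerateColumnError(OwaciError):
    """A factor column is constant and cannot be min-max normalized.

    The remedy is to remove the factor from the registry for this run.
    """


class DegenerateSeriesError(OwaciError):
    """A series has zero rank variance (all values tied)."""


class InfeasibleEmphasisError(OwaciError):
    """The requested emphasis would zero out every ordered position."""


class SingularCovarianceError(OwaciError):
    """The bivariate sample covariance is singular; distances are undefined."""


class FeasibilityError(OwaciError):
    """A synthetic-data target cannot be met under the configured noise."""
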