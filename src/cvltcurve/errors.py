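"""Exception hierarchy for cvltcurve.

All errors derive from :class:`CvltCurveError` so callers can catch the
package's failures with a single except clause. Input-validation problems
subclass :class:`ValueError` as well, matching numpy/scipy convention.
"""


class CvltCurveError(Exception):
    """Base class for all cvltcurve errors."""


class ParameterError(CvltCurveError, ValueError):
    """Model parameters violate their domain (e.g. learning rate B2 <= 0)."""


class InputError(CvltCurveError, ValueError):
    """Input data violate a precondition (length, range, monotonicity...)."""


class DegenerateComparisonError(CvltCurveError, ValueError):
    """A coefficient comparison is undefined (zero or missing standard error)."""


class NoStructureError(CvltCurveError, ValueError):
    """Clustering requested on data with no structure (all values identical)."""


class TieError(CvltCurveError, ValueError):
    """Cluster naming is ambiguous because both cluster means are equal."""


class CollinearityError(CvltCurveError, ValueError):
    """Pooled within-group covariance is singular; names offending predictors."""


class SchemaError(CvltCurveError, ValueError):
    """A cohort table violates the expected CSV schema."""
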