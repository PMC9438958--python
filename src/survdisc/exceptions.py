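"""Exception hierarchy.

All survdisc errors derive from :class:`SurvdiscError` so callers can catch
the package's failures with one clause; each subclass marks a distinct
failure mode (invalid data, misaligned ids, undefined measure, improper
curve, invalid evaluation plan).
"""


class SurvdiscError(Exception):
    """Base class for all survdisc errors."""


class DataValidationError(SurvdiscError, ValueError):
    """An input object violates a structural invariant (range, monotonicity, NaN)."""


class IdAlignmentError(SurvdiscError, ValueError):
    """Subject ids do not match across the objects being combined."""


class UndefinedMeasureError(SurvdiscError, ValueError):
    """A measure has an empty denominator (no comparable pairs, no cases/controls)."""


class ImproperCurveError(SurvdiscError, ValueError):
    """An operation requires a proper survival curve (reaching 0) and got one that does not."""


class PlanError(SurvdiscError, ValueError):
    """An evaluation plan is malformed or demands an incommensurable comparison."""
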