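"""Package-specific error types.

The audit distinguishes *undefined* quantities (a metric that has no value
for a degenerate subgroup, e.g. a balanced error rate when one outcome class
is absent) from ordinary invalid-input errors.  Callers that build report
tables catch :class:`UndefinedMetricError` and record the subgroup as
undefined rather than dropping it silently.
"""


class FairdemError(Exception):
    """Base class for all package errors."""


class InfeasibleConcordanceError(FairdemError):
    """The configured SES concordance targets are jointly infeasible."""


class UndefinedMetricError(FairdemError):
    """A requested statistic has no defined value for this input.

    Raised e.g. for a balanced error rate on a subgroup missing an outcome
    class, a concordance conditioned on an empty low-SES set, or a relative
    difference with a zero denominator.
    """


class MeasureRangeError(FairdemError):
    """An SES measure value lies outside the measure's declared range."""

    def __init__(self, measure: str, value) -> None:
        super().__init__(f"value {value!r} out of range for SES measure {measure!r}")
        self.measure = measure
        self.value = value


class InfeasibleBalanceError(FairdemError):
    """A protected-attribute balancing constraint cannot be satisfied."""
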