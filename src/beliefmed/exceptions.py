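"""Exception hierarchy for beliefmed.

All errors derive from :class:`BeliefmedError` so callers (and the CLI)
can distinguish package errors from programming errors.
"""


class BeliefmedError(Exception):
    """Base class for all beliefmed errors."""


class SchemaError(BeliefmedError):
    """An expected column is missing from the input table."""


class ParseError(BeliefmedError):
    """A cell that must be numeric could not be parsed.

    Carries ``row`` (0-based index into the input, excluding the header)
    and ``column`` attributes when available.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class UnsupportedDesignError(BeliefmedError):
    """The cue column does not define a two-level contrast."""


class BeliefStructureError(BeliefmedError):
    """Global-belief structure violated: belief varies within a
    (participant, cue level) cell.  Use the item-varying mediator path
    instead of a global-belief summary."""


class UndefinedStatisticError(BeliefmedError):
    """A test statistic is undefined (e.g. zero-variance differences)."""


class DegenerateDesignError(BeliefmedError):
    """The design matrix for a model is degenerate (constant moderator,
    zero contrast column, ...)."""


class RankDeficiencyError(BeliefmedError):
    """Fixed-effects design matrix is rank deficient; names the
    collinear terms."""

    def __init__(self, message: str, terms: list[str] | None = None):
        super().__init__(message)
        self.terms = terms or []


class EstimationFailureError(BeliefmedError):
    """A mixed-model fit failed in a way that cannot be repaired by
    random-effect pruning."""


class GateStopError(BeliefmedError):
    """The paired t-test gate failed under ``enforce`` policy."""
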