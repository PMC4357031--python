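"""Exception hierarchy.

Three error classes matter to callers: data errors (parsing/validation of
rating files), computation errors (items that cannot be aggregated), and
plain argument errors. The CLI maps them to distinct exit codes.
"""


class CPIError(Exception):
    """Base class for all package errors."""


class ArgumentError(CPIError, ValueError):
    """Invalid argument (bad k, incoherent cut-offs, out-of-range value)."""


class DataError(CPIError):
    """Base for errors raised while reading or validating rating data."""


class ParseError(DataError):
    """Malformed rating file; message names the offending row (and column)."""


class ValidationError(DataError):
    """Structurally invalid panel, e.g. duplicated (stakeholder, item, criterion)."""


class ComputationError(CPIError):
    """Base for errors raised during aggregation."""


class NoResponsesError(ComputationError):
    """An (item, criterion) cell has zero non-missing scores."""

    def __init__(self, item_id, criterion):
        self.item_id = item_id
        self.criterion = criterion
        super().__init__(
            f"item {item_id!r}: no non-missing scores for criterion {criterion!r}"
        )


class IncompleteItemError(ComputationError):
    """A CPI was requested from an incomplete set of criterion means."""


class DegenerateItemError(ComputationError):
    """Bootstrap replicates for an item stayed degenerate past the redraw guard."""
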