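"""Exception hierarchy for matchqual.

All package errors derive from :class:`MatchQualError` so callers can catch
one base class at pipeline boundaries.
"""


class MatchQualError(Exception):
    """Base class for all matchqual errors."""


class SchemaError(MatchQualError):
    """An input table is missing required columns or is otherwise malformed."""


class RowValidationError(MatchQualError):
    """One or more rows failed field-level validation.

    Carries ``rows``: a list of ``(row_index, column, message)`` tuples.
    """

    def __init__(self, rows):
        self.rows = list(rows)
        lines = "; ".join(f"row {r}: {c}: {m}" for r, c, m in self.rows)
        super().__init__(f"{len(self.rows)} invalid row(s): {lines}")


class LinkageError(MatchQualError):
    """A matched-set reference is dangling or violates cardinality rules."""


class DataError(MatchQualError):
    """A derived quantity is impossible given its inputs (e.g. negative duration)."""


class InsufficientDataError(MatchQualError):
    """Too few usable observations to run the requested test."""


class CapacityError(MatchQualError):
    """Exact enumeration was requested but the arrangement count exceeds the cap."""


class ConfigError(MatchQualError):
    """A generator or analysis configuration is infeasible or inconsistent."""


class DomainError(MatchQualError):
    """An arithmetic input is outside its domain (zero denominator, negative rate)."""


class SpecError(MatchQualError):
    """A value does not conform to its declared VariableSpec."""
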