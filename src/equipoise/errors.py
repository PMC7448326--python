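"""Exception hierarchy for validation and analysis failures.

``ValidationError`` covers malformed inputs (CLI exit code 1);
``AnalysisError`` covers degenerate statistics (CLI exit code 2).
"""


class EquipoiseError(Exception):
    """Base class for all package errors."""


class ValidationError(EquipoiseError):
    """Input data violates a structural invariant."""


class DuplicateRecordError(ValidationError):
    """Two records share the same (rater, case, session, question) key."""

    def __init__(self, key: tuple):
        self.key = key
        super().__init__(
            f"duplicate decision record for (rater={key[0]!r}, case={key[1]!r}, "
            f"session={key[2]!r}, question={key[3]!r})"
        )


class EmptyInputError(ValidationError):
    """No records to analyze."""


class MissingColumnError(ValidationError):
    """A required CSV column is absent."""


class AnalysisError(EquipoiseError):
    """An agreement statistic cannot be computed on this slice."""


class DegenerateChanceError(AnalysisError):
    """Chance agreement is 1 (all assignments in one category); kappa undefined."""


class InsufficientCasesError(AnalysisError):
    """Too few cases with at least two raters to estimate agreement."""
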