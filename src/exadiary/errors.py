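"""Exception hierarchy for the exadiary package."""


class ExadiaryError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ExadiaryError):
    """A delimited input file violates the documented schema.

    Carries enough context (row number, column name) to locate the
    offending cell in the source file.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column


class ValidationError(ExadiaryError):
    """Inputs violate a precondition of an analysis operation."""


class GenerationError(ExadiaryError):
    """The synthetic-cohort configuration cannot be realised."""


class SeparationError(ExadiaryError):
    """Complete or quasi-complete separation in a logistic fit."""


class SingularDesignError(ExadiaryError):
    """Design matrix is rank-deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is singular; collinear columns: " + ", ".join(self.columns)
        )
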