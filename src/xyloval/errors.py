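"""Exception hierarchy shared across the validation pipeline."""


class XylovalError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(XylovalError):
    """A mandatory column is missing or the file cannot be parsed as a table."""


class ValidationError(XylovalError):
    """Row-level data violates an invariant; message lists offending rows/ids."""

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class ParseError(XylovalError):
    """A cell could not be converted to the expected type."""


class InsufficientDataError(XylovalError):
    """Fewer observations than the estimator requires."""


class DegenerateInputError(XylovalError):
    """Input is formally valid but makes the computation undefined
    (e.g. calibrator response equal to the blank, zero denominator)."""
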