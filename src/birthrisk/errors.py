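"""Exception hierarchy shared across the pipeline."""


class BirthRiskError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(BirthRiskError):
    """A record violates a domain invariant.

    ``field`` names the offending field; ``row`` carries the 0-based row
    index when the record came from a tabular input.
    """

    def __init__(self, message: str, *, field: str | None = None,
                 row: int | None = None):
        self.field = field
        self.row = row
        prefix = ""
        if row is not None:
            prefix += f"row {row}: "
        if field is not None:
            prefix += f"field '{field}': "
        super().__init__(prefix + message)


class SchemaError(BirthRiskError):
    """A tabular input does not match its declared schema."""


class FitError(BirthRiskError):
    """A model cannot be fitted on the given design."""


class ConvergenceError(FitError):
    """REML optimisation failed; carries the last iterate and trace."""

    def __init__(self, message: str, *, last_lambda: float | None = None,
                 trace: list | None = None):
        self.last_lambda = last_lambda
        self.trace = trace or []
        super().__init__(message)


class PredictionError(BirthRiskError):
    """A prediction request cannot be satisfied."""
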