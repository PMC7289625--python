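"""Exception hierarchy for vo2verify.

Every validation failure carries enough context (row / column coordinates
where applicable) for a user to locate the offending record.
"""


class VO2VerifyError(Exception):
    """Base class for all package errors."""


class FormatError(VO2VerifyError):
    """A file is structurally malformed (spacing, columns, encoding)."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        coords = []
        if row is not None:
            coords.append(f"row {row}")
        if column is not None:
            coords.append(f"column {column!r}")
        if coords:
            message = f"{message} ({', '.join(coords)})"
        super().__init__(message)


class ValidationError(VO2VerifyError):
    """Data violate a domain invariant (negative gas values, bad ranges)."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        coords = []
        if row is not None:
            coords.append(f"row {row}")
        if column is not None:
            coords.append(f"column {column!r}")
        if coords:
            message = f"{message} ({', '.join(coords)})"
        super().__init__(message)


class InsufficientDataError(VO2VerifyError):
    """Series too short for the requested window computation."""


class UndefinedPlateauError(VO2VerifyError):
    """Plateau status cannot be determined (fewer than two full minutes)."""


class UndefinedROCError(VO2VerifyError):
    """ROC analysis requested with only one outcome class present."""


class LeakageError(VO2VerifyError):
    """A derivation-cohort subject appeared in the hold-out cohort."""


class ConfigurationError(VO2VerifyError):
    """Invalid configuration value (unknown variable, bad simplex, ...)."""
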