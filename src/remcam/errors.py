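"""Exception types shared across the package."""


class RemcamError(Exception):
    """Base class for all package errors."""


class ValidationError(RemcamError):
    """Raised when input tables or parameters fail validation.

    Carries an optional list of offending row labels so callers (and the CLI)
    can report exactly which records were rejected.
    """

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class EstimationError(RemcamError):
    """Raised when an estimation step cannot proceed (e.g. empty speed pool)."""
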