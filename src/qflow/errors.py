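"""Exception types shared across the package."""


class QFlowError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(QFlowError, ValueError):
    """An argument violates an operation's preconditions."""


class SchemaError(QFlowError, KeyError):
    """An event table is missing a required channel or column."""


class InsufficientDataError(QFlowError, ValueError):
    """Not enough events to perform the requested computation."""


class InsufficientCellsError(InsufficientDataError):
    """No gated cells for a subject; carries the subject id."""

    def __init__(self, subject_id: str, message: str | None = None):
        self.subject_id = subject_id
        super().__init__(message or f"no gated cells for subject {subject_id!r}")


class CalibrationFailureError(QFlowError, RuntimeError):
    """Bead levels could not be separated into four clusters."""


class DegenerateCurveError(QFlowError, ZeroDivisionError):
    """A calibration curve with zero slope cannot be inverted."""


class NoSignalError(QFlowError, ValueError):
    """All receptor counts are non-positive; nothing to fit in log space."""


class MissingCellError(QFlowError, ValueError):
    """A requested factorial cell has no observations / is inestimable."""
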