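"""Exception hierarchy shared across the package.

Batch processing treats most of these as data (recorded per cell), so the
classes carry enough context — file coordinates, character positions,
offending text — to be rendered into a report without a traceback.
"""

from __future__ import annotations


class DVHPointsError(Exception):
    """Base class for all errors raised by dvhpoints."""


class FileFormatError(DVHPointsError):
    """A DVH CSV file (or request file) violates the expected dialect.

    ``row`` and ``column`` are 1-based coordinates of the offending cell
    when known.
    """

    def __init__(self, message: str, *, row: int | None = None,
                 column: int | None = None) -> None:
        loc = ""
        if row is not None:
            loc = f" (row {row}" + (f", column {column}" if column else "") + ")"
        super().__init__(message + loc)
        self.row = row
        self.column = column


class DVHValidationError(DVHPointsError):
    """Parsed data violates a DVH invariant (monotonicity, sign, duplicates)."""


class HeaderDoseError(FileFormatError):
    """Cell C1/D1 text could not be parsed as a dose."""

    def __init__(self, text: str) -> None:
        super().__init__(f"cannot parse header dose cell: {text!r}")
        self.text = text


class ExpressionError(DVHPointsError):
    """Base for dose/volume-point expression problems."""


class ExpressionSyntaxError(ExpressionError):
    """Text outside the expression grammar; ``position`` is 0-based."""

    def __init__(self, text: str, position: int, message: str) -> None:
        super().__init__(f"{message} at position {position} in {text!r}")
        self.text = text
        self.position = position


class UnitPairingError(ExpressionError):
    """A syntactically valid expression uses an illegal unit combination."""


class ExpressionValueError(ExpressionError):
    """The numeric argument of an expression is out of range (must be > 0)."""


class RequestError(DVHPointsError):
    """A review-request file could not be loaded; message lists line numbers."""


class EvaluationError(DVHPointsError):
    """Base for failures while evaluating a point on a structure."""


class DomainError(EvaluationError):
    """Query argument outside the mathematical domain (negative dose/volume)."""


class DegenerateStructureError(EvaluationError):
    """Structure too small (or empty) for the requested metric."""


class MissingReferenceError(EvaluationError):
    """No reference/prescription dose resolvable for a case that needs one."""
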