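"""The dose/volume-point expression language.

A dose/volume point is a scalar summary of a cumulative DVH, written in a
compact syntax that keeps absolute and relative quantities unambiguous:

=================  ====================================================
``D(Gy)40(cc)``    dose in Gy covering 40 cc of the structure
``D(Gy)40(%)``     dose in Gy covering 40% of the structure
``D(%)40(cc)``     dose as % of the reference dose covering 40 cc
``D(%)40(%)``      dose as % of the reference dose covering 40% volume
``V(cc)40(Gy)``    volume in cc receiving at least 40 Gy
``V(cc)40(%)``     volume in cc receiving ≥ 40% of the reference dose
``V(%)40(Gy)``     volume as % of the structure receiving ≥ 40 Gy
``V(%)40(%)``      volume % receiving ≥ 40% of the reference dose
``Dmax``           RTOG near-maximum dose, identical to D(Gy)0.03(cc)
``Dmin``           RTOG near-minimum dose (dose at total volume − 0.03 cc)
``Dmean``          mean structure dose
=================  ====================================================

Any metric whose value is an absolute dose (``D(Gy)…``, ``Dmax``, ``Dmin``,
``Dmean``) may carry the suffix ``/Rx`` (divide by the prescription dose,
yielding a dimensionless ratio), optionally followed by ``× 100`` (``x``,
``X`` and ``*`` are accepted spellings) to express the ratio in percent.

Grammar (whitespace between tokens ignored)::

    expr   := base suffix?
    base   := ('D' | 'V') '(' unit ')' number '(' unit ')'
            | 'Dmax' | 'Dmin' | 'Dmean'
    suffix := '/Rx' mult?
    mult   := ('×' | 'x' | 'X' | '*') '100'

Unit keywords (``Gy``, ``cc``, ``%``) and metric names are case-sensitive;
numbers are positive decimals with an optional fractional part (no
scientific notation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .errors import ExpressionSyntaxError, ExpressionValueError, UnitPairingError

__all__ = [
    "DoseVolumePoint",
    "parse_expression",
    "validate_request_syntax",
    "format_expression",
    "NAMED_METRICS",
]

NAMED_METRICS = ("Dmax", "Dmin", "Dmean")

# Legal unit pairings per metric letter: output unit -> allowed arg units.
_PAIRINGS: dict[str, dict[str, tuple[str, ...]]] = {
    "D": {"Gy": ("cc", "%"), "%": ("cc", "%")},
    "V": {"cc": ("Gy", "%"), "%": ("Gy", "%")},
}


@dataclass(frozen=True)
class DoseVolumePoint:
    """Parsed AST of one dose/volume-point expression.

    Named metrics (Dmax, Dmin, Dmean) carry no units or argument; the
    arithmetic suffix ``times_100`` implies ``divide_by_rx``.
    """

    metric: str                    # 'D' | 'V' | 'Dmax' | 'Dmin' | 'Dmean'
    out_unit: str | None = None    # D: Gy|% ; V: cc|% ; named: None
    arg_value: float | None = None
    arg_unit: str | None = None    # D: cc|% ; V: Gy|% ; named: None
    divide_by_rx: bool = False
    times_100: bool = False
    source_text: str = ""

    def __post_init__(self) -> None:
        if self.metric in NAMED_METRICS:
            if (self.out_unit, self.arg_value, self.arg_unit) != (None, None, None):
                raise UnitPairingError(
                    f"{self.metric} takes no units or argument"
                )
        elif self.metric in ("D", "V"):
            allowed = _PAIRINGS[self.metric]
            if self.out_unit not in allowed:
                raise UnitPairingError(
                    f"{self.metric} cannot output unit {self.out_unit!r}"
                )
            if self.arg_unit not in allowed[self.out_unit]:
                raise UnitPairingError(
                    f"{self.metric}({self.out_unit}) cannot take an argument "
                    f"in {self.arg_unit!r}"
                )
            if self.arg_value is None or not self.arg_value > 0:
                raise ExpressionValueError(
                    f"argument must be > 0, got {self.arg_value}"
                )
        else:
            raise UnitPairingError(f"unknown metric {self.metric!r}")
        if self.times_100 and not self.divide_by_rx:
            raise UnitPairingError("'× 100' is only valid after '/Rx'")
        if self.divide_by_rx and not self.is_absolute_dose:
            raise UnitPairingError(
                "'/Rx' applies only to metrics valued in absolute dose (Gy)"
            )

    @property
    def is_absolute_dose(self) -> bool:
        """True when the base metric's value is an absolute dose in Gy."""
        return self.metric in NAMED_METRICS or (
            self.metric == "D" and self.out_unit == "Gy"
        )

    @property
    def result_unit(self) -> str:
        """Unit of the evaluated value: Gy, cc, %, or dimensionless."""
        if self.divide_by_rx:
            return "%" if self.times_100 else "dimensionless"
        if self.metric in NAMED_METRICS:
            return "Gy"
        return self.out_unit  # type: ignore[return-value]


_NUMBER_RE = re.compile(r"\d+(?:\.\d+)?")
_MULT_CHARS = ("×", "x", "X", "*")


class _Scanner:
    """Character scanner that skips whitespace and tracks positions."""

    def __init__(self, text: str) -> None:
        self.text = text
        self.pos = 0

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def eof(self) -> bool:
        self.skip_ws()
        return self.pos >= len(self.text)

    def accept(self, literal: str) -> bool:
        self.skip_ws()
        if self.text.startswith(literal, self.pos):
            self.pos += len(literal)
            return True
        return False

    def expect(self, literal: str, what: str) -> None:
        self.skip_ws()
        if not self.accept(literal):
            raise ExpressionSyntaxError(self.text, self.pos, f"expected {what}")

    def number(self) -> float:
        self.skip_ws()
        m = _NUMBER_RE.match(self.text, self.pos)
        if m is None:
            raise ExpressionSyntaxError(self.text, self.pos, "expected a number")
        self.pos = m.end()
        return float(m.group())

    def unit(self) -> str:
        self.skip_ws()
        for u in ("Gy", "cc", "%"):
            if self.accept(u):
                return u
        raise ExpressionSyntaxError(
            self.text, self.pos, "expected a unit (Gy, cc or %)"
        )


def parse_expression(text: str) -> DoseVolumePoint:
    """Parse one expression string into a :class:`DoseVolumePoint`.

    Raises
    ------
    ExpressionSyntaxError
        For text outside the grammar (with the failing character position).
    UnitPairingError
        For an illegal unit combination, e.g. ``V(Gy)40(cc)``.
    ExpressionValueError
        For a non-positive numeric argument.
    """
    if not text or not text.strip():
        raise ExpressionSyntaxError(text, 0, "empty expression")
    sc = _Scanner(text)
    sc.skip_ws()

    # Named metrics first: 'Dmax' must win over metric letter 'D'.
    metric = None
    for name in NAMED_METRICS:
        if sc.accept(name):
            metric = name
            break
    if metric is not None:
        point = DoseVolumePoint(metric=metric, source_text=text)
    elif sc.accept("D") or sc.accept("V"):
        letter = text[sc.pos - 1]
        sc.expect("(", "'('")
        out_unit = sc.unit()
        sc.expect(")", "')'")
        arg = sc.number()
        sc.expect("(", "'('")
        arg_unit = sc.unit()
        sc.expect(")", "')'")
        point = DoseVolumePoint(
            metric=letter, out_unit=out_unit, arg_value=arg,
            arg_unit=arg_unit, source_text=text,
        )
    else:
        raise ExpressionSyntaxError(
            text, sc.pos, "expected D, V, Dmax, Dmin or Dmean"
        )

    if sc.accept("/"):
        sc.expect("Rx", "'Rx'")
        times_100 = False
        sc.skip_ws()
        if sc.pos < len(sc.text) and sc.text[sc.pos] in _MULT_CHARS:
            sc.pos += 1
            sc.skip_ws()
            if not sc.accept("100"):
                raise ExpressionSyntaxError(sc.text, sc.pos, "expected '100'")
            times_100 = True
        point = replace(point, divide_by_rx=True, times_100=times_100)

    if not sc.eof():
        raise ExpressionSyntaxError(sc.text, sc.pos, "unexpected trailing text")
    return point


def validate_request_syntax(
    expressions: list[str],
) -> list[tuple[int, str]]:
    """Check a list of expression strings; never raises.

    Returns an empty list iff every expression parses, otherwise one
    ``(index, error description)`` entry per failure.
    """
    failures: list[tuple[int, str]] = []
    for i, text in enumerate(expressions):
        try:
            parse_expression(text)
        except (ExpressionSyntaxError, UnitPairingError,
                ExpressionValueError) as exc:
            failures.append((i, str(exc)))
    return failures


def _fmt_number(x: float) -> str:
    """Plain decimal rendering: no exponent, no trailing zeros."""
    s = format(float(x), ".12f").rstrip("0").rstrip(".")
    return s if s else "0"


def format_expression(point: DoseVolumePoint) -> str:
    """Canonical text of a point; inverse of :func:`parse_expression`.

    The only internal whitespace is around the multiplication sign, as the
    syntax is conventionally printed (``Dmean/Rx × 100``).
    """
    if point.metric in NAMED_METRICS:
        base = point.metric
    else:
        base = (f"{point.metric}({point.out_unit})"
                f"{_fmt_number(point.arg_value)}({point.arg_unit})")
    if point.divide_by_rx:
        base += "/Rx"
        if point.times_100:
            base += " × 100"
    return base
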