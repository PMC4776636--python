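"""Review requests and cohort batch evaluation.

A review request pairs structure names with dose/volume points and lives in
a plain-text file, one line per structure::

    # LU001-style request
    PTV: D(%)95(%), Dmax, Dmean/Rx × 100
    Lungs: V(%)20(Gy), Dmean

Blank lines and lines starting with ``#`` are ignored.  The colon separates
the structure name (which therefore may not contain ``:`` or ``,``) from a
comma-separated list of expressions.

``run_batch`` drives the evaluation loop: cases outer, request rows inner,
points innermost, resolving the reference dose once per case.  At the batch
level errors are data, not exceptions — every (case, structure, point)
triple produces exactly one cell, either a value or an absence carrying its
reason, so a QA batch always completes and reports everything it could
compute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    DVHPointsError,
    EvaluationError,
    MissingReferenceError,
    RequestError,
)
from .evaluator import (
    MetricValue,
    RunSettings,
    evaluate,
    resolve_reference_dose,
    resolve_rx_dose,
)
from .expressions import (
    DoseVolumePoint,
    format_expression,
    parse_expression,
    validate_request_syntax,
)
from .io import DVHCase, StructureDVH

__all__ = [
    "ReviewRequest",
    "ResultCell",
    "ResultTable",
    "load_request",
    "save_request",
    "match_structure",
    "run_batch",
    "STRUCTURE_MISSING",
    "EVALUATION_ERROR",
]

STRUCTURE_MISSING = "structure_missing"
EVALUATION_ERROR = "evaluation_error"


@dataclass(frozen=True)
class ReviewRequest:
    """Ordered list of (structure name, dose/volume points) rows."""

    rows: tuple[tuple[str, tuple[DoseVolumePoint, ...]], ...]

    def __post_init__(self) -> None:
        rows = tuple((name, tuple(pts)) for name, pts in self.rows)
        object.__setattr__(self, "rows", rows)
        if not rows:
            raise RequestError("a review request needs at least one row")
        for name, pts in rows:
            if not name or not name.strip():
                raise RequestError("structure name must be non-empty")
            if ":" in name or "," in name:
                raise RequestError(
                    f"structure name {name!r} may not contain ':' or ','"
                )
            if not pts:
                raise RequestError(
                    f"structure {name!r} has no dose/volume points"
                )

    @property
    def n_points(self) -> int:
        return sum(len(pts) for _, pts in self.rows)


@dataclass(frozen=True)
class ResultCell:
    """One evaluated cell, or an absence marker with its reason."""

    value: MetricValue | None
    status: str = "ok"          # 'ok' | 'structure_missing' | 'evaluation_error'
    detail: str = ""
    naming_warning: bool = False

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class ResultTable:
    """Evaluated values per case × request row × point.

    ``cells`` maps ``(case_id, structure_name, expression_text)`` to a
    :class:`ResultCell`; ``case_ids`` preserves input case order and
    ``request`` the row/point order, so reports are deterministic.
    """

    request: ReviewRequest
    case_ids: list[str] = field(default_factory=list)
    cells: dict[tuple[str, str, str], ResultCell] = field(default_factory=dict)

    def cell(self, case_id: str, structure: str, expr: str) -> ResultCell:
        return self.cells[(case_id, structure, expr)]

    def column_values(self, structure: str, expr: str) -> list[float]:
        """Values of one (structure, expression) column, absences excluded."""
        out = []
        for cid in self.case_ids:
            c = self.cells[(cid, structure, expr)]
            if c.ok:
                out.append(c.value.value)
        return out


def load_request(path: str | Path) -> ReviewRequest:
    """Load a plain-text review request; raises :class:`RequestError`
    listing every offending line if any expression fails to parse."""
    path = Path(path)
    rows: list[tuple[str, tuple[DoseVolumePoint, ...]]] = []
    problems: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8-sig") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                problems.append(f"line {lineno}: expected 'Structure: expr, ...'")
                continue
            name, _, rest = line.partition(":")
            name = name.strip()
            if not name:
                problems.append(f"line {lineno}: empty structure name")
                continue
            if name in seen:
                problems.append(f"line {lineno}: duplicate structure {name!r}")
                continue
            seen.add(name)
            exprs = [e.strip() for e in rest.split(",")]
            failures = validate_request_syntax(exprs)
            if failures:
                for idx, msg in failures:
                    problems.append(f"line {lineno}, expression {idx + 1}: {msg}")
                continue
            rows.append((name, tuple(parse_expression(e) for e in exprs)))
    if problems:
        raise RequestError(
            f"{path.name}: " + "; ".join(problems)
        )
    if not rows:
        raise RequestError(f"{path.name}: no request rows found")
    return ReviewRequest(tuple(rows))


def save_request(request: ReviewRequest, path: str | Path) -> None:
    """Write a request in canonical text; :func:`load_request` inverts it."""
    lines = [
        f"{name}: " + ", ".join(format_expression(p) for p in pts)
        for name, pts in request.rows
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def match_structure(
    case: DVHCase, name: str
) -> tuple[StructureDVH | None, bool]:
    """Find a structure by name; returns ``(structure, naming_warning)``.

    Exact match after whitespace trimming wins; otherwise a case-insensitive
    match returns the structure with a naming-deviation warning (the
    structure-naming convention is case-sensitive); otherwise ``(None,
    False)``.
    """
    want = name.strip()
    for s in case.structures:
        if s.name.strip() == want:
            return s, False
    folded = want.casefold()
    for s in case.structures:
        if s.name.strip().casefold() == folded:
            return s, True
    return None, False


def run_batch(
    cases: list[DVHCase],
    request: ReviewRequest,
    settings: RunSettings,
) -> ResultTable:
    """Evaluate every request point on every case.

    The reference dose is resolved once per case; a case where it cannot be
    resolved still gets all its reference-free cells computed, with the
    reference-dependent ones marked ``evaluation_error``.
    """
    if not cases:
        raise DVHPointsError("run_batch needs at least one case")
    table = ResultTable(request=request)
    for case in cases:
        table.case_ids.append(case.case_id)
        try:
            ref = resolve_reference_dose(case, settings)
            ref_problem = ""
        except MissingReferenceError as exc:
            ref, ref_problem = None, str(exc)
        rx = resolve_rx_dose(case, settings)
        for name, points in request.rows:
            structure, warned = match_structure(case, name)
            for p in points:
                key = (case.case_id, name, format_expression(p))
                if structure is None:
                    table.cells[key] = ResultCell(
                        None, STRUCTURE_MISSING,
                        f"structure {name!r} not in case {case.case_id!r}",
                    )
                    continue
                try:
                    mv = evaluate(p, structure, ref, rx)
                    table.cells[key] = ResultCell(mv, naming_warning=warned)
                except EvaluationError as exc:
                    detail = ref_problem if (
                        ref_problem and isinstance(exc, MissingReferenceError)
                    ) else str(exc)
                    table.cells[key] = ResultCell(
                        None, EVALUATION_ERROR, detail
                    )
    return table
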