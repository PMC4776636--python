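"""Cohort quantile statistics and the spreadsheet report.

The report mirrors the three regions of the tool's spreadsheet output: the
review request echoed at the top, the evaluated values case-per-row in the
middle, and the cohort statistics block at the bottom.  One sheet is
produced per requested structure plus an overview sheet covering every
(structure, expression) pair.

The statistics are the 1, 2, 5, 10, 15, 85, 90, 95, 98 and 99% quantiles
of each dose/volume point across the cohort — the tails that matter for
judging the spread of plan quality across enrolling institutions — plus
the count of contributing cases.  Absent cells (missing structures,
evaluation failures) are excluded from the statistics and surface through
the count column and an annotation column; they are never imputed.

The quantile convention is the linear order-statistic interpolation
``h = (n−1)·p/100 + 1`` on 1-based sorted ranks, stated as a formula so any
implementation reproduces it bit-for-bit.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

from .batch import ResultTable, ReviewRequest
from .errors import DomainError, DVHPointsError
from .expressions import format_expression

__all__ = [
    "QUANTILE_LEVELS",
    "quantile",
    "Sheet",
    "SummaryReport",
    "build_report",
    "write_report",
]

#: Cohort quantile levels (%), ascending; fixed roster of ten.
QUANTILE_LEVELS: tuple[float, ...] = (1, 2, 5, 10, 15, 85, 90, 95, 98, 99)


def quantile(values: list[float], level: float) -> float:
    """Order-statistic quantile with linear interpolation.

    On sorted values x₍₁₎ ≤ … ≤ x₍ₙ₎ (1-based ranks), the rank is
    ``h = (n−1)·level/100 + 1`` and the result is
    ``x₍⌊h⌋₎ + (h−⌊h⌋)·(x₍⌊h⌋₊₁₎ − x₍⌊h⌋₎)``.

    Raises
    ------
    DVHPointsError
        For an empty value list.
    DomainError
        For a level outside (0, 100).
    """
    if not values:
        raise DVHPointsError("quantile of an empty value list")
    if not 0 < level < 100:
        raise DomainError(f"quantile level must be in (0, 100), got {level}")
    xs = sorted(float(v) for v in values)
    n = len(xs)
    h = (n - 1) * level / 100.0 + 1.0
    lo = math.floor(h)
    frac = h - lo
    if lo >= n:
        return xs[-1]
    return xs[lo - 1] + frac * (xs[lo] - xs[lo - 1]) if frac else xs[lo - 1]


@dataclass
class Sheet:
    """One spreadsheet: header columns, case rows, and the stats block.

    ``columns`` are (structure, expression-text) pairs; ``rows`` holds one
    entry per case: the case id, the cell values (``None`` for absences),
    and the annotation string collecting absence reasons for that row.
    ``stats`` maps each quantile level to per-column values (``None`` where
    a column has no contributing cases) and ``counts`` gives per-column
    contributing-case counts.
    """

    name: str
    request_lines: list[str]
    columns: list[tuple[str, str]]
    rows: list[tuple[str, list[float | None], str]]
    stats: dict[float, list[float | None]]
    counts: list[int]


@dataclass
class SummaryReport:
    """Per-structure sheets plus the overview sheet, in request order."""

    sheets: list[Sheet] = field(default_factory=list)

    @property
    def overview(self) -> Sheet:
        return self.sheets[-1]


def _request_lines(request: ReviewRequest) -> list[str]:
    return [
        f"{name}: " + ", ".join(format_expression(p) for p in pts)
        for name, pts in request.rows
    ]


def _build_sheet(
    name: str,
    columns: list[tuple[str, str]],
    table: ResultTable,
    request_lines: list[str],
) -> Sheet:
    rows: list[tuple[str, list[float | None], str]] = []
    for cid in table.case_ids:
        values: list[float | None] = []
        notes: list[str] = []
        for structure, expr in columns:
            cell = table.cell(cid, structure, expr)
            if cell.ok:
                values.append(cell.value.value)
                if cell.naming_warning:
                    notes.append(f"{structure}: naming deviation")
            else:
                values.append(None)
                notes.append(f"{structure}/{expr}: {cell.status}")
        rows.append((cid, values, "; ".join(notes)))

    stats: dict[float, list[float | None]] = {lv: [] for lv in QUANTILE_LEVELS}
    counts: list[int] = []
    for structure, expr in columns:
        col = table.column_values(structure, expr)
        counts.append(len(col))
        for lv in QUANTILE_LEVELS:
            stats[lv].append(quantile(col, lv) if col else None)
    return Sheet(name=name, request_lines=request_lines, columns=columns,
                 rows=rows, stats=stats, counts=counts)


def build_report(table: ResultTable, request: ReviewRequest) -> SummaryReport:
    """Assemble the summary report: one sheet per structure + overview."""
    req_lines = _request_lines(request)
    report = SummaryReport()
    all_columns: list[tuple[str, str]] = []
    for name, points in request.rows:
        columns = [(name, format_expression(p)) for p in points]
        all_columns.extend(columns)
        report.sheets.append(_build_sheet(name, columns, table, req_lines))
    report.sheets.append(_build_sheet("overview", all_columns, table, req_lines))
    return report


def _display(x: float | None, full: bool = False) -> str:
    if x is None:
        return ""
    return format(x, ".10g") if full else format(x, ".2f")


def sanitize_name(name: str) -> str:
    """Filesystem-safe sheet/file name: non-alphanumerics become '_'."""
    return re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_") or "structure"


def _sheet_rows(sheet: Sheet, full: bool) -> list[list[str]]:
    out: list[list[str]] = [["# request"]]
    out += [[f"# {line}"] for line in sheet.request_lines]
    out.append([])
    header = ["case"]
    for structure, expr in sheet.columns:
        label = expr if sheet.name != "overview" else f"{structure} | {expr}"
        header.append(label)
    header.append("annotations")
    out.append(header)
    for cid, values, notes in sheet.rows:
        out.append([cid] + [_display(v, full) for v in values] + [notes])
    out.append([])
    out.append(["quantile"] + [""] * len(sheet.columns))
    for lv in QUANTILE_LEVELS:
        out.append([f"{lv:g}%"] + [_display(v, full) for v in sheet.stats[lv]])
    out.append(["n"] + [str(c) for c in sheet.counts])
    return out


def write_report(
    report: SummaryReport,
    path: str | Path,
    format: str = "csv",
    full_precision: bool = False,
) -> None:
    """Write the report to ``path``.

    ``csv`` mode writes a directory with one ``<structure>.csv`` per sheet
    plus ``overview.csv``, numbers rendered with 2 decimal places; with
    ``full_precision`` a ``*_full.csv`` sidecar per sheet preserves full
    numeric precision.  ``xlsx`` mode writes one workbook with one
    worksheet per sheet.
    """
    import csv as _csv

    path = Path(path)
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for sheet in report.sheets:
            stem = ("overview" if sheet.name == "overview"
                    else sanitize_name(sheet.name))
            targets = [(path / f"{stem}.csv", False)]
            if full_precision:
                targets.append((path / f"{stem}_full.csv", True))
            for target, full in targets:
                with open(target, "w", newline="", encoding="utf-8") as fh:
                    _csv.writer(fh).writerows(_sheet_rows(sheet, full))
    elif format == "xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        wb.remove(wb.active)
        for sheet in report.sheets:
            title = ("overview" if sheet.name == "overview"
                     else sanitize_name(sheet.name))[:31]
            ws = wb.create_sheet(title=title)
            for row in _sheet_rows(sheet, full=False):
                ws.append(row if row else [None])
        wb.save(path)
    else:
        raise DVHPointsError(f"unknown report format {format!r}")
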