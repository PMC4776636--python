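"""Reading and writing cumulative-DVH CSV files (MIM-export dialect).

Layout of a DVH CSV file::

    row 1:  <patient/site ID>, <ignored>, [Rx cell], [Dmax cell], ...
    row 2:  <label over dose column>, <structure 1>, <structure 2>, ...
    row 3+: dose, volume_1, volume_2, ...

The dose column is in Gy on an arbitrary strictly increasing grid; volume
columns are absolute volumes in cc, non-increasing down the column
(cumulative convention: volume receiving *at least* the row's dose).  The
third field of row 1 ("cell C1") optionally carries a per-case prescription
dose, the fourth ("cell D1") a per-case global maximum dose; both accept a
long form (``Rx = 60 Gy`` / ``Dmax = 80 Gy``) or a bare number.

Dialect: RFC 4180, UTF-8 (BOM tolerated), '.' decimal separator regardless
of locale.  Trailing empty rows and columns are stripped before validation.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DVHValidationError, FileFormatError, HeaderDoseError

__all__ = [
    "StructureDVH",
    "DVHCase",
    "parse_header_dose",
    "read_dvh_file",
    "write_dvh_file",
]


@dataclass(frozen=True)
class StructureDVH:
    """One structure's cumulative DVH: dose grid (Gy) + absolute volumes (cc).

    ``cum_volume[i]`` is the volume receiving at least ``dose_grid[i]``; the
    total structure volume is by definition the volume at the lowest grid
    dose.
    """

    name: str
    dose_grid: np.ndarray
    cum_volume: np.ndarray

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose_grid, dtype=float)
        vol = np.asarray(self.cum_volume, dtype=float)
        object.__setattr__(self, "dose_grid", dose)
        object.__setattr__(self, "cum_volume", vol)
        if not self.name or not self.name.strip():
            raise DVHValidationError("structure name must be non-empty")
        if dose.ndim != 1 or vol.ndim != 1 or dose.shape != vol.shape:
            raise DVHValidationError(
                f"structure {self.name!r}: dose grid and volumes must be "
                f"1-D arrays of equal length"
            )
        if dose.size < 2:
            raise DVHValidationError(
                f"structure {self.name!r}: need at least 2 grid points"
            )
        if dose[0] < 0 or np.any(np.diff(dose) <= 0):
            raise DVHValidationError(
                f"structure {self.name!r}: dose grid must be non-negative "
                f"and strictly increasing"
            )
        if np.any(vol < 0):
            raise DVHValidationError(
                f"structure {self.name!r}: negative volume value"
            )
        if np.any(np.diff(vol) > 0):
            raise DVHValidationError(
                f"structure {self.name!r}: cumulative volume must be "
                f"non-increasing along the dose grid"
            )

    @property
    def total_volume(self) -> float:
        """Total structure volume in cc (cumulative volume at the grid start)."""
        return float(self.cum_volume[0])


@dataclass(frozen=True)
class DVHCase:
    """One patient/case: ID, optional header doses, and its structure DVHs."""

    case_id: str
    structures: tuple[StructureDVH, ...] = field(default_factory=tuple)
    rx_dose: float | None = None
    global_max_dose: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "structures", tuple(self.structures))
        if not self.case_id or not self.case_id.strip():
            raise DVHValidationError("case_id must be non-empty")
        for attr in ("rx_dose", "global_max_dose"):
            v = getattr(self, attr)
            if v is not None and not v > 0:
                raise DVHValidationError(f"{attr} must be > 0, got {v}")
        names = [s.name.strip() for s in self.structures]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DVHValidationError(f"duplicate structure name(s): {dupes}")

    def structure_names(self) -> list[str]:
        return [s.name for s in self.structures]


# Long form "Rx = 60 Gy" / "Dmax = 80 Gy" (key and units case-insensitive,
# whitespace-tolerant) or short form: a bare number.
_HEADER_DOSE_RE = re.compile(
    r"^\s*(?:(?:rx|dmax)\s*=\s*)?(\d+(?:\.\d+)?)\s*(?:gy)?\s*$",
    re.IGNORECASE,
)


def parse_header_dose(cell_text: str) -> float:
    """Parse a C1/D1 header cell into a dose in Gy.

    Accepts ``"Rx = 60 Gy"``, ``"Dmax = 80 Gy"``, or the short form ``"60"``.

    Raises
    ------
    HeaderDoseError
        If the text matches neither form.
    """
    if not cell_text or not cell_text.strip():
        raise HeaderDoseError(cell_text)
    m = _HEADER_DOSE_RE.match(cell_text)
    if m is None:
        raise HeaderDoseError(cell_text)
    return float(m.group(1))


def _strip_trailing_empty(rows: list[list[str]]) -> list[list[str]]:
    rows = [list(r) for r in rows]
    while rows and all(c.strip() == "" for c in rows[-1]):
        rows.pop()
    for r in rows:
        while r and r[-1].strip() == "":
            r.pop()
    return rows


def read_dvh_file(path: str | Path) -> DVHCase:
    """Read a DVH CSV file into a :class:`DVHCase`.

    Column 1 of rows 3+ becomes the shared dose grid; every further column
    becomes one :class:`StructureDVH` named by row 2.  Non-empty C1/D1
    header cells are parsed with :func:`parse_header_dose`.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8-sig") as fh:
        rows = _strip_trailing_empty(list(csv.reader(fh)))
    if len(rows) < 3:
        raise FileFormatError(f"{path.name}: need at least 3 rows, got {len(rows)}")

    header, names_row = rows[0], rows[1]
    if not header or not header[0].strip():
        raise FileFormatError(f"{path.name}: missing patient/site ID", row=1, column=1)
    case_id = header[0].strip()
    rx = None
    if len(header) >= 3 and header[2].strip():
        rx = parse_header_dose(header[2])
    dmax = None
    if len(header) >= 4 and header[3].strip():
        dmax = parse_header_dose(header[3])

    ncol = len(names_row)
    if ncol < 2:
        raise FileFormatError(
            f"{path.name}: need a dose column plus at least one structure",
            row=2,
        )
    # Row-2 cell above the dose column may be blank or any label; ignored.
    names = [c.strip() for c in names_row[1:]]
    for j, name in enumerate(names, start=2):
        if not name:
            raise FileFormatError(
                f"{path.name}: empty structure name", row=2, column=j
            )

    data = np.empty((len(rows) - 2, ncol), dtype=float)
    for i, row in enumerate(rows[2:], start=3):
        if len(row) != ncol:
            raise FileFormatError(
                f"{path.name}: expected {ncol} fields, got {len(row)}", row=i
            )
        for j, cell in enumerate(row, start=1):
            try:
                data[i - 3, j - 1] = float(cell)
            except ValueError:
                raise FileFormatError(
                    f"{path.name}: non-numeric cell {cell!r}", row=i, column=j
                ) from None

    dose = data[:, 0]
    if np.any(np.diff(dose) <= 0):
        raise DVHValidationError(
            f"{path.name}: dose column is not strictly increasing"
        )
    structures = [
        StructureDVH(name=names[k], dose_grid=dose, cum_volume=data[:, k + 1])
        for k in range(len(names))
    ]
    return DVHCase(case_id=case_id, structures=tuple(structures),
                   rx_dose=rx, global_max_dose=dmax)


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def write_dvh_file(case: DVHCase, path: str | Path) -> None:
    """Write ``case`` as a DVH CSV file that :func:`read_dvh_file` round-trips.

    All structures in a case share one dose grid; the first structure's grid
    is written as the dose column.
    """
    if not case.structures:
        raise DVHValidationError("cannot write a case with no structures")
    grid = case.structures[0].dose_grid
    for s in case.structures[1:]:
        if s.dose_grid.shape != grid.shape or not np.array_equal(s.dose_grid, grid):
            raise DVHValidationError(
                f"structure {s.name!r} does not share the case dose grid"
            )
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([
            case.case_id,
            "",
            f"Rx = {_fmt(case.rx_dose)} Gy" if case.rx_dose is not None else "",
            f"Dmax = {_fmt(case.global_max_dose)} Gy"
            if case.global_max_dose is not None else "",
        ])
        w.writerow(["Dose (Gy)"] + [s.name for s in case.structures])
        for i in range(grid.size):
            w.writerow([_fmt(grid[i])] +
                       [_fmt(s.cum_volume[i]) for s in case.structures])
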