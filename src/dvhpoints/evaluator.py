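"""Evaluating dose/volume points on cumulative DVH curves.

The exported DVH is taken as exactly piecewise linear between grid points,
so every query is answered by linear interpolation — no smoothing, no
resampling.  Conventions for the awkward cases:

* ``dose_at_volume`` uses the supremum on flat segments: the *largest* dose
  whose interpolated volume still covers the query volume.  This matches
  the "dose that covers v" semantics and keeps the RTOG near-maximum
  well-defined near the curve tail.
* A query volume above the total volume yields 0 Gy with an
  ``out_of_range`` flag instead of an error, so one bad request cannot
  abort a batch.
* A curve whose last volume is still positive (export truncated before the
  curve reached zero) is treated as dropping to zero immediately after the
  last grid dose; results touching that region carry a
  ``structure_truncated`` flag.
* The mean dose is the trapezoidal integral of the cumulative curve divided
  by the total volume — exact under the piecewise-linear assumption.

Percent units are resolved against a :class:`ReferenceDose` (prescription
or per-plan maximum); the ``/Rx`` suffix always divides by the
*prescription* dose regardless of the reference mode, which only governs
percent-dose conversions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateStructureError,
    DomainError,
    MissingReferenceError,
)
from .expressions import DoseVolumePoint
from .io import DVHCase, StructureDVH

__all__ = [
    "ReferenceDose",
    "RunSettings",
    "MetricValue",
    "RTOG_POINT_VOLUME_CC",
    "volume_at_dose",
    "dose_at_volume",
    "mean_dose",
    "rtog_max",
    "rtog_min",
    "evaluate",
    "resolve_reference_dose",
    "resolve_rx_dose",
]

#: Minimum clinically meaningful point volume per the RTOG convention:
#: near-max/near-min doses are read 0.03 cc in from the curve ends.
RTOG_POINT_VOLUME_CC = 0.03

OUT_OF_RANGE = "out_of_range"
STRUCTURE_TRUNCATED = "structure_truncated"


@dataclass(frozen=True)
class ReferenceDose:
    """The dose defining 100% for percent-dose conversions."""

    mode: str     # 'prescription' | 'maximum'
    value: float  # Gy

    def __post_init__(self) -> None:
        if self.mode not in ("prescription", "maximum"):
            raise ValueError(f"unknown reference mode {self.mode!r}")
        if not self.value > 0:
            raise ValueError(f"reference dose must be > 0, got {self.value}")


@dataclass(frozen=True)
class RunSettings:
    """Run-level settings: reference mode and optional global prescription.

    ``global_rx_dose`` applies to every case that does not carry its own
    prescription dose in cell C1; a C1 value overrides it.
    """

    reference_mode: str = "prescription"   # 'prescription' | 'maximum'
    global_rx_dose: float | None = None    # Gy

    def __post_init__(self) -> None:
        if self.reference_mode not in ("prescription", "maximum"):
            raise ValueError(f"unknown reference mode {self.reference_mode!r}")
        if self.global_rx_dose is not None and not self.global_rx_dose > 0:
            raise ValueError("global_rx_dose must be > 0")


@dataclass(frozen=True)
class MetricValue:
    """An evaluated dose/volume point: value, unit, and quality flags."""

    value: float
    unit: str                       # 'Gy' | '%' | 'cc' | 'dimensionless'
    flags: frozenset[str] = frozenset()


def _truncated(s: StructureDVH) -> bool:
    return float(s.cum_volume[-1]) > 0.0


def volume_at_dose(s: StructureDVH, d: float) -> MetricValue:
    """Absolute volume (cc) receiving at least dose ``d`` (Gy).

    Below the grid the whole structure is covered; above the grid the last
    exported volume is returned (zero for a complete curve), flagged
    ``structure_truncated`` when it is still positive.
    """
    if d < 0:
        raise DomainError(f"dose must be >= 0, got {d}")
    flags = set()
    if d > float(s.dose_grid[-1]) and _truncated(s):
        flags.add(STRUCTURE_TRUNCATED)
    v = float(np.interp(d, s.dose_grid, s.cum_volume,
                        left=s.total_volume, right=float(s.cum_volume[-1])))
    return MetricValue(v, "cc", frozenset(flags))


def dose_at_volume(s: StructureDVH, v: float) -> MetricValue:
    """Largest dose (Gy) still covering volume ``v`` (cc): sup{d : V(d) ≥ v}.

    ``v == 0`` maps to the last grid dose, ``v == total_volume`` to the
    first; ``v > total_volume`` yields 0 Gy flagged ``out_of_range``.
    """
    if v < 0:
        raise DomainError(f"volume must be >= 0, got {v}")
    vols = s.cum_volume
    doses = s.dose_grid
    if v > s.total_volume:
        return MetricValue(0.0, "Gy", frozenset({OUT_OF_RANGE}))
    # Reversed arrays: volumes non-decreasing, doses decreasing.
    vr = vols[::-1]
    dr = doses[::-1]
    i = int(np.searchsorted(vr, v, side="left"))
    if i >= vr.size:          # v == total_volume and grid start is unique max
        return MetricValue(float(doses[0]), "Gy", frozenset())
    flags = set()
    if i == 0:
        # v at or below the last exported volume: the supremum on the grid
        # is the last grid dose (curve treated as dropping to 0 just after).
        if _truncated(s):
            flags.add(STRUCTURE_TRUNCATED)
        return MetricValue(float(doses[-1]), "Gy", frozenset(flags))
    if vr[i] == v:
        return MetricValue(float(dr[i]), "Gy", frozenset())
    # vr[i-1] < v < vr[i]: interpolate inside the segment.
    frac = (vr[i] - v) / (vr[i] - vr[i - 1])
    d = float(dr[i] + frac * (dr[i - 1] - dr[i]))
    return MetricValue(d, "Gy", frozenset())


def mean_dose(s: StructureDVH) -> MetricValue:
    """Mean structure dose (Gy): ∫V(d)dd / V(0) by the trapezoid rule."""
    if s.total_volume <= 0:
        raise DegenerateStructureError(
            f"structure {s.name!r} has zero total volume"
        )
    flags = set()
    if _truncated(s):
        flags.add(STRUCTURE_TRUNCATED)
    m = float(np.trapezoid(s.cum_volume, s.dose_grid)) / s.total_volume
    return MetricValue(m, "Gy", frozenset(flags))


def rtog_max(s: StructureDVH) -> MetricValue:
    """RTOG near-maximum dose: the dose covering 0.03 cc, D(Gy)0.03(cc)."""
    if s.total_volume < RTOG_POINT_VOLUME_CC:
        raise DegenerateStructureError(
            f"structure {s.name!r}: RTOG Dmax (dose covering 0.03 cc) "
            f"needs total volume >= 0.03 cc, got {s.total_volume} cc"
        )
    return dose_at_volume(s, RTOG_POINT_VOLUME_CC)


def rtog_min(s: StructureDVH) -> MetricValue:
    """RTOG near-minimum dose: the dose at total volume − 0.03 cc."""
    if s.total_volume < RTOG_POINT_VOLUME_CC:
        raise DegenerateStructureError(
            f"structure {s.name!r}: RTOG Dmin needs total volume >= 0.03 cc, "
            f"got {s.total_volume} cc"
        )
    return dose_at_volume(s, s.total_volume - RTOG_POINT_VOLUME_CC)


def evaluate(
    point: DoseVolumePoint,
    s: StructureDVH,
    ref: ReferenceDose | None = None,
    rx_dose: float | None = None,
) -> MetricValue:
    """Evaluate one dose/volume point on one structure.

    ``ref`` supplies the 100% level for percent-dose units and is required
    whenever the expression uses ``%`` on a dose; ``rx_dose`` is the
    prescription dose used by the ``/Rx`` suffix.  When ``rx_dose`` is not
    given and the reference mode is ``prescription``, ``ref.value`` stands
    in for it.

    Raises
    ------
    MissingReferenceError
        If a percent-dose unit or ``/Rx`` is requested without the needed
        reference/prescription dose.
    """
    def need_ref() -> float:
        if ref is None:
            raise MissingReferenceError(
                f"{point.source_text or point.metric}: percent dose needs a "
                f"reference dose"
            )
        return ref.value

    flags: set[str] = set()

    if point.metric in ("Dmax", "Dmin", "Dmean"):
        inner = {"Dmax": rtog_max, "Dmin": rtog_min, "Dmean": mean_dose}[
            point.metric](s)
        value, unit = inner.value, "Gy"
        flags |= inner.flags
    elif point.metric == "D":
        arg_cc = (point.arg_value if point.arg_unit == "cc"
                  else point.arg_value / 100.0 * s.total_volume)
        inner = dose_at_volume(s, arg_cc)
        flags |= inner.flags
        if point.out_unit == "%":
            value, unit = inner.value / need_ref() * 100.0, "%"
        else:
            value, unit = inner.value, "Gy"
    else:  # 'V'
        arg_gy = (point.arg_value if point.arg_unit == "Gy"
                  else point.arg_value / 100.0 * need_ref())
        inner = volume_at_dose(s, arg_gy)
        flags |= inner.flags
        if point.out_unit == "%":
            if s.total_volume <= 0:
                raise DegenerateStructureError(
                    f"structure {s.name!r} has zero total volume"
                )
            value, unit = inner.value / s.total_volume * 100.0, "%"
        else:
            value, unit = inner.value, "cc"

    if point.divide_by_rx:
        rx = rx_dose
        if rx is None and ref is not None and ref.mode == "prescription":
            rx = ref.value
        if rx is None:
            raise MissingReferenceError(
                f"{point.source_text or point.metric}: '/Rx' needs a "
                f"prescription dose"
            )
        value = value / rx
        unit = "dimensionless"
        if point.times_100:
            value *= 100.0
            unit = "%"

    return MetricValue(value, unit, frozenset(flags))


def resolve_reference_dose(case: DVHCase, settings: RunSettings) -> ReferenceDose:
    """Resolve the 100% reference dose for one case.

    Mode ``prescription``: the case's C1 value if present, else the global
    prescription dose.  Mode ``maximum``: the case's D1 value (required per
    case, since plans do not share a global maximum dose).
    """
    if settings.reference_mode == "prescription":
        value = case.rx_dose if case.rx_dose is not None else settings.global_rx_dose
        if value is None:
            raise MissingReferenceError(
                f"case {case.case_id!r}: no prescription dose in cell C1 and "
                f"no global prescription dose set"
            )
        return ReferenceDose("prescription", value)
    if case.global_max_dose is None:
        raise MissingReferenceError(
            f"case {case.case_id!r}: reference mode 'maximum' needs a "
            f"per-case maximum dose in cell D1"
        )
    return ReferenceDose("maximum", case.global_max_dose)


def resolve_rx_dose(case: DVHCase, settings: RunSettings) -> float | None:
    """Prescription dose for '/Rx': per-case C1 value over the global one."""
    return case.rx_dose if case.rx_dose is not None else settings.global_rx_dose
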