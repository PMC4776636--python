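"""Synthetic DVH cases with closed-form ground truth.

Every other module is testable without clinical data: this module builds
cumulative DVH curves from three analytic dose-profile families and records
the exact metric values implied by each curve alongside the case.

Profiles (V₀ = total volume in cc):

* ``uniform(d₀)`` — the whole structure receives exactly d₀ Gy:
  V(d) = V₀ for d < d₀, 0 beyond.  On the grid the step is realised as a
  symmetric ramp of half-width 1e-6 Gy centred on d₀, which keeps the
  trapezoidal mean exactly d₀ and the RTOG near-max/near-min within 2e-6 Gy
  of d₀.
* ``linear(D₀)`` — dose falls off linearly: V(d) = V₀·(1 − d/D₀)₊.  D₀ is
  inserted into the grid so the piecewise-linear curve is exact.
* ``sigmoid(d₅₀, slope)`` — logistic fall-off V(d) = V₀ / (1 + exp(slope·(d
  − d₅₀))), a smooth stand-in for realistic target coverage curves.  Its
  ground truths are computed by a high-resolution numeric oracle (10⁵-point
  resampling), independent of the evaluator's interpolation path.

Cohorts jitter the per-structure parameters multiplicatively with a
lognormal factor (volumes and doses stay positive by construction) and are
fully deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import DVHPointsError
from .io import DVHCase, StructureDVH, write_dvh_file

__all__ = [
    "UniformProfile",
    "LinearProfile",
    "SigmoidProfile",
    "StructureSpec",
    "SyntheticSpec",
    "generate_case",
    "generate_cohort",
    "random_piecewise_linear_dvh",
]

_STEP_HALF_WIDTH = 1e-6  # Gy; ramp half-width realising the uniform step
_RTOG_CC = 0.03


@dataclass(frozen=True)
class UniformProfile:
    """Whole structure at one dose d₀ (Gy)."""

    d0: float

    @property
    def max_dose(self) -> float:
        return self.d0


@dataclass(frozen=True)
class LinearProfile:
    """Linear fall-off reaching zero volume at D₀ (Gy)."""

    d0: float

    @property
    def max_dose(self) -> float:
        return self.d0


@dataclass(frozen=True)
class SigmoidProfile:
    """Logistic fall-off with midpoint d₅₀ (Gy) and slope (1/Gy)."""

    d50: float
    slope: float

    @property
    def max_dose(self) -> float:
        # Volume is negligible (< 1e-9 V0) beyond d50 + ~21/slope.
        return self.d50 + 21.0 / self.slope


Profile = UniformProfile | LinearProfile | SigmoidProfile


@dataclass(frozen=True)
class StructureSpec:
    name: str
    total_volume: float  # cc
    profile: Profile


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic case (or the base of a cohort)."""

    structures: tuple[StructureSpec, ...]
    rx_dose: float | None = None
    global_max_dose: float | None = None
    grid_max: float | None = None   # Gy; default 1.2 × max profile dose
    grid_step: float = 0.1          # Gy
    case_id: str = "SYN-001"

    def __post_init__(self) -> None:
        object.__setattr__(self, "structures", tuple(self.structures))
        if not self.structures:
            raise DVHPointsError("synthetic spec needs at least one structure")
        for s in self.structures:
            if not s.total_volume > _RTOG_CC:
                raise DVHPointsError(
                    f"structure {s.name!r}: total volume must exceed "
                    f"{_RTOG_CC} cc"
                )
        if not self.grid_step > 0:
            raise DVHPointsError("grid step must be > 0")

    def resolved_grid_max(self) -> float:
        if self.grid_max is not None:
            return self.grid_max
        return 1.2 * max(s.profile.max_dose for s in self.structures)


def _profile_curve(profile: Profile, v0: float,
                   grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (grid, volumes) for one profile; may refine the grid."""
    if isinstance(profile, UniformProfile):
        h = _STEP_HALF_WIDTH
        keep = (grid < profile.d0 - h) | (grid > profile.d0 + h)
        g = np.sort(np.concatenate(
            [grid[keep], [profile.d0 - h, profile.d0 + h]]))
        v = np.where(g <= profile.d0 - h, v0,
                     np.where(g >= profile.d0 + h, 0.0,
                              v0 * (profile.d0 + h - g) / (2 * h)))
        return g, v
    if isinstance(profile, LinearProfile):
        if profile.d0 not in grid:
            g = np.sort(np.append(grid[grid != profile.d0], profile.d0))
        else:
            g = grid
        v = v0 * np.clip(1.0 - g / profile.d0, 0.0, None)
        return g, v
    v = v0 / (1.0 + np.exp(profile.slope * (grid - profile.d50)))
    return grid, v


def _truths_uniform(p: UniformProfile, v0: float) -> dict[str, float]:
    return {
        "Dmean": p.d0,
        "rtog_max": p.d0,
        "rtog_min": p.d0,
        f"D@{v0 / 2:.10g}cc": p.d0,
        f"V@{p.d0 / 2:.10g}Gy": v0,
    }


def _truths_linear(p: LinearProfile, v0: float) -> dict[str, float]:
    return {
        "Dmean": p.d0 / 2.0,
        "rtog_max": p.d0 * (1.0 - _RTOG_CC / v0),
        "rtog_min": p.d0 * _RTOG_CC / v0,
        f"D@{v0 / 2:.10g}cc": p.d0 / 2.0,
        f"V@{p.d0 / 2:.10g}Gy": v0 / 2.0,
    }


def _truths_sigmoid(p: SigmoidProfile, v0: float) -> dict[str, float]:
    """Numeric oracle on a dense 10⁵-point grid, independent of the
    evaluator: trapezoidal mean and bisection-free inversion by resampling."""
    d = np.linspace(0.0, p.max_dose, 100_000)
    v = v0 / (1.0 + np.exp(np.clip(p.slope * (d - p.d50), -700, 700)))
    total = v[0]
    mean = float(np.trapezoid(v, d) / total)

    def dose_at(volume: float) -> float:
        # v is strictly decreasing; invert by interpolation on reversed axes
        return float(np.interp(volume, v[::-1], d[::-1]))

    return {
        "Dmean": mean,
        "rtog_max": dose_at(_RTOG_CC),
        "rtog_min": dose_at(total - _RTOG_CC),
        f"D@{total / 2:.10g}cc": dose_at(total / 2),
        f"V@{p.d50:.10g}Gy": v0 / 2.0,  # logistic midpoint symmetry
    }


def generate_case(spec: SyntheticSpec) -> tuple[DVHCase, dict[str, dict[str, float]]]:
    """Build one :class:`DVHCase` plus its ground-truth metric map.

    The truth map is keyed by structure name; entries are closed-form
    (uniform/linear) or dense-grid numeric (sigmoid) values for ``Dmean``,
    ``rtog_max``, ``rtog_min`` and a dose/volume probe each
    (``D@<v>cc`` → Gy, ``V@<d>Gy`` → cc).
    """
    grid_max = spec.resolved_grid_max()
    base_grid = np.arange(0.0, grid_max + spec.grid_step / 2, spec.grid_step)
    # Refine once so all structures share a single grid.
    grid = base_grid
    for s in spec.structures:
        grid, _ = _profile_curve(s.profile, s.total_volume, grid)

    structures = []
    truths: dict[str, dict[str, float]] = {}
    for s in spec.structures:
        g, v = _profile_curve(s.profile, s.total_volume, grid)
        if not np.array_equal(g, grid):  # pragma: no cover - defensive
            raise DVHPointsError("internal error: structures must share a grid")
        structures.append(StructureDVH(name=s.name, dose_grid=grid, cum_volume=v))
        if isinstance(s.profile, UniformProfile):
            truths[s.name] = _truths_uniform(s.profile, s.total_volume)
        elif isinstance(s.profile, LinearProfile):
            truths[s.name] = _truths_linear(s.profile, s.total_volume)
        else:
            truths[s.name] = _truths_sigmoid(s.profile, s.total_volume)
    case = DVHCase(case_id=spec.case_id, structures=tuple(structures),
                   rx_dose=spec.rx_dose, global_max_dose=spec.global_max_dose)
    return case, truths


def _jitter_profile(profile: Profile, factor: float) -> Profile:
    if isinstance(profile, SigmoidProfile):
        return replace(profile, d50=profile.d50 * factor)
    return replace(profile, d0=profile.d0 * factor)


def generate_cohort(
    n: int,
    base: SyntheticSpec,
    jitter: float,
    seed: int,
) -> list[tuple[DVHCase, dict[str, dict[str, float]]]]:
    """Generate ``n`` cases jittered around ``base``; deterministic per seed.

    Each structure's volume and dose-scale parameter are multiplied by an
    independent lognormal factor with the given relative spread (sigma of
    log); ``jitter=0`` reproduces the base exactly.  The base grid span is
    widened by a 6-sigma margin so jittered profiles stay covered.
    """
    if n < 1:
        raise DVHPointsError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    grid_max = base.resolved_grid_max() * (1.0 + 6.0 * jitter)
    for k in range(n):
        structs = []
        for s in base.structures:
            fv = float(rng.lognormal(0.0, jitter)) if jitter else 1.0
            fd = float(rng.lognormal(0.0, jitter)) if jitter else 1.0
            structs.append(StructureSpec(
                name=s.name,
                total_volume=s.total_volume * fv,
                profile=_jitter_profile(s.profile, fd),
            ))
        spec = replace(base, structures=tuple(structs),
                       grid_max=grid_max, case_id=f"SYN-{k + 1:03d}")
        out.append(generate_case(spec))
    return out


def random_piecewise_linear_dvh(
    rng: np.random.Generator,
    name: str = "random",
    n_knots: int = 12,
    max_dose: float = 80.0,
    total_volume: float = 100.0,
) -> StructureDVH:
    """A random valid cumulative DVH: sorted knots, non-increasing volumes.

    Used as the test workhorse for oracle comparisons; the curve always
    starts at ``total_volume`` and ends at 0 cc.
    """
    doses = np.sort(rng.uniform(0.0, max_dose, size=n_knots))
    doses[0] = 0.0
    # Strictly increasing: nudge duplicates apart.
    eps = max_dose * 1e-9
    for i in range(1, doses.size):
        if doses[i] <= doses[i - 1]:
            doses[i] = doses[i - 1] + eps
    drops = rng.dirichlet(np.ones(n_knots - 1)) * total_volume
    vols = total_volume - np.concatenate([[0.0], np.cumsum(drops)])
    vols[-1] = 0.0
    vols = np.maximum(vols, 0.0)
    return StructureDVH(name=name, dose_grid=doses, cum_volume=vols)


def write_cohort(
    cohort: list[tuple[DVHCase, dict[str, dict[str, float]]]],
    out_dir: str | Path,
) -> list[Path]:
    """Write cohort cases as DVH CSV files plus a ``truths.csv`` sidecar."""
    import csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    with open(out_dir / "truths.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "structure", "metric", "value"])
        for case, truths in cohort:
            p = out_dir / f"{case.case_id}.csv"
            write_dvh_file(case, p)
            paths.append(p)
            for sname, metrics in truths.items():
                for metric, value in metrics.items():
                    w.writerow([case.case_id, sname, metric,
                                format(value, ".10g")])
    return paths
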