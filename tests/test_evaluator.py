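"""Evaluator tests: closed forms, conventions, and a brute-force oracle.

The oracle resamples each piecewise-linear curve onto a dense grid
(10^5 uniform points refined with the original knots, so the resampled
curve is exact) and answers queries by linear scan — independent of the
evaluator's searchsorted/interp path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dvhpoints import (
    DegenerateStructureError,
    DomainError,
    DVHCase,
    MissingReferenceError,
    ReferenceDose,
    RunSettings,
    StructureDVH,
    dose_at_volume,
    evaluate,
    mean_dose,
    parse_expression,
    random_piecewise_linear_dvh,
    resolve_reference_dose,
    rtog_max,
    rtog_min,
    volume_at_dose,
)

REF = ReferenceDose("prescription", 50.0)


# --- independent dense-grid oracle ------------------------------------------

def _dense_curve(s: StructureDVH, n: int = 100_000):
    d = np.union1d(np.linspace(s.dose_grid[0], s.dose_grid[-1], n), s.dose_grid)
    v = np.interp(d, s.dose_grid, s.cum_volume)
    return d, v


def oracle_volume_at_dose(s: StructureDVH, dose: float) -> float:
    d, v = _dense_curve(s)
    if dose <= d[0]:
        return float(v[0])
    if dose >= d[-1]:
        return float(v[-1])
    return float(np.interp(dose, d, v))


def oracle_dose_at_volume(s: StructureDVH, vol: float) -> float:
    """Supremum by linear scan: last dense index whose volume still >= vol."""
    d, v = _dense_curve(s)
    if vol > v[0]:
        return 0.0
    idx = np.nonzero(v >= vol)[0]
    i = int(idx[-1])
    if i == d.size - 1 or v[i] == vol:
        return float(d[i])
    # v[i] > vol > v[i+1]: interpolate inside the dense segment
    return float(d[i] + (v[i] - vol) / (v[i] - v[i + 1]) * (d[i + 1] - d[i]))


def oracle_mean_dose(s: StructureDVH) -> float:
    """Mean of the implied differential DVH: bin mass x midpoint dose."""
    d, v = _dense_curve(s)
    mass = v[:-1] - v[1:]
    mid = 0.5 * (d[:-1] + d[1:])
    return float(np.sum(mass * mid) / v[0])


# --- closed forms on the linear family ---------------------------------------

class TestLinearClosedForms:
    def test_volume_at_dose(self, linear_dvh):
        assert volume_at_dose(linear_dvh, 60.0).value == pytest.approx(40.0, abs=1e-12)
        assert volume_at_dose(linear_dvh, 0.0).value == 100.0

    def test_dose_at_volume(self, linear_dvh):
        assert dose_at_volume(linear_dvh, 40.0).value == pytest.approx(60.0, abs=1e-12)
        assert dose_at_volume(linear_dvh, 100.0).value == 0.0   # first grid dose
        assert dose_at_volume(linear_dvh, 0.0).value == 100.0   # last grid dose

    def test_mean_dose(self, linear_dvh):
        assert mean_dose(linear_dvh).value == pytest.approx(50.0, rel=1e-12)

    def test_rtog_extremes(self, linear_dvh):
        assert rtog_max(linear_dvh).value == pytest.approx(99.97, rel=1e-12)
        assert rtog_min(linear_dvh).value == pytest.approx(0.03, abs=1e-9)

    def test_uniform_structure_rtog_min_approx_max(self):
        eps = 1e-6
        s = StructureDVH("u", np.array([0.0, 60.0, 60.0 + eps]),
                         np.array([30.0, 30.0, 0.0]))
        assert abs(rtog_min(s).value - rtog_max(s).value) < eps
        assert mean_dose(s).value == pytest.approx(60.0, rel=1e-6)


class TestConventions:
    def test_flat_segment_supremum(self, flat_dvh):
        # Largest dose still covering 50 cc is the end of the flat segment.
        assert dose_at_volume(flat_dvh, 50.0).value == 10.0

    def test_volume_above_total_is_flagged_zero(self, linear_dvh):
        mv = dose_at_volume(linear_dvh, 150.0)
        assert mv.value == 0.0 and "out_of_range" in mv.flags

    def test_truncated_curve_flags(self, truncated_dvh):
        assert "structure_truncated" in volume_at_dose(truncated_dvh, 70.0).flags
        assert "structure_truncated" in mean_dose(truncated_dvh).flags
        assert "structure_truncated" in dose_at_volume(truncated_dvh, 5.0).flags
        # Queries inside the exported range are unaffected.
        assert volume_at_dose(truncated_dvh, 30.0).flags == frozenset()

    def test_negative_queries_rejected(self, linear_dvh):
        with pytest.raises(DomainError):
            volume_at_dose(linear_dvh, -1.0)
        with pytest.raises(DomainError):
            dose_at_volume(linear_dvh, -1.0)

    def test_degenerate_structure_for_rtog(self):
        tiny = StructureDVH("tiny", np.array([0.0, 1.0]), np.array([0.01, 0.0]))
        with pytest.raises(DegenerateStructureError):
            rtog_max(tiny)
        with pytest.raises(DegenerateStructureError):
            rtog_min(tiny)


# --- oracle comparison on random curves --------------------------------------

class TestOracle:
    def test_queries_match_brute_force(self, rng):
        for _ in range(10):
            s = random_piecewise_linear_dvh(rng)
            doses = rng.uniform(0.0, 80.0, size=100)
            for d in doses:
                got = volume_at_dose(s, float(d)).value
                assert got == pytest.approx(oracle_volume_at_dose(s, d),
                                            rel=1e-9, abs=1e-9)
            vols = rng.uniform(0.0, 100.0, size=100)
            for v in vols:
                got = dose_at_volume(s, float(v)).value
                assert got == pytest.approx(oracle_dose_at_volume(s, v),
                                            rel=1e-9, abs=1e-9)

    def test_mean_matches_differential_route(self, rng):
        for _ in range(10):
            s = random_piecewise_linear_dvh(rng)
            assert mean_dose(s).value == pytest.approx(oracle_mean_dose(s),
                                                       rel=1e-9)

    def test_rtog_identity_is_bitwise(self, rng):
        expr = parse_expression("D(Gy)0.03(cc)")
        for _ in range(20):
            s = random_piecewise_linear_dvh(rng)
            assert rtog_max(s).value == evaluate(expr, s).value
            assert rtog_min(s).value == dose_at_volume(
                s, s.total_volume - 0.03).value


# --- property tests -----------------------------------------------------------

@settings(derandomize=True, max_examples=50)
@given(seed=st.integers(0, 2**31 - 1),
       frac=st.floats(0.01, 0.99))
def test_inverse_consistency(seed, frac):
    """V(D(v)) == v strictly inside the range of a strictly decreasing DVH."""
    s = random_piecewise_linear_dvh(np.random.default_rng(seed))
    v = frac * s.total_volume
    d = dose_at_volume(s, v).value
    assert volume_at_dose(s, d).value == pytest.approx(v, rel=1e-9, abs=1e-9)


@settings(derandomize=True, max_examples=30)
@given(seed=st.integers(0, 2**31 - 1))
def test_monotonicity(seed):
    s = random_piecewise_linear_dvh(np.random.default_rng(seed))
    doses = np.linspace(0, 85, 40)
    vols = [volume_at_dose(s, float(d)).value for d in doses]
    assert all(a >= b - 1e-12 for a, b in zip(vols, vols[1:]))
    queries = np.linspace(0, s.total_volume, 40)
    ds = [dose_at_volume(s, float(v)).value for v in queries]
    assert all(a >= b - 1e-12 for a, b in zip(ds, ds[1:]))


# --- expression evaluation ----------------------------------------------------

class TestEvaluate:
    @pytest.mark.parametrize("text,expected,unit", [
        ("D(Gy)40(cc)", 60.0, "Gy"),
        ("D(Gy)40(%)", 60.0, "Gy"),        # 40% of 100 cc = 40 cc
        ("D(%)40(cc)", 120.0, "%"),        # 60 Gy / 50 Gy x 100
        ("D(%)40(%)", 120.0, "%"),
        ("V(cc)40(Gy)", 60.0, "cc"),
        ("V(cc)40(%)", 80.0, "cc"),        # 40% of 50 Gy = 20 Gy
        ("V(%)40(Gy)", 60.0, "%"),
        ("V(%)40(%)", 80.0, "%"),
        ("Dmax", 99.97, "Gy"),
        ("Dmin", 0.03, "Gy"),
        ("Dmean", 50.0, "Gy"),
        ("Dmean/Rx", 1.0, "dimensionless"),
        ("Dmean/Rx × 100", 100.0, "%"),
    ])
    def test_roster_on_linear_dvh(self, linear_dvh, text, expected, unit):
        mv = evaluate(parse_expression(text), linear_dvh, REF)
        assert mv.value == pytest.approx(expected, rel=1e-9, abs=1e-9)
        assert mv.unit == unit

    def test_percent_absolute_duality(self, rng):
        for _ in range(5):
            s = random_piecewise_linear_dvh(rng)
            rel = evaluate(parse_expression("V(%)30(Gy)"), s, REF).value
            absv = evaluate(parse_expression("V(cc)30(Gy)"), s, REF).value
            assert rel == pytest.approx(absv / s.total_volume * 100, rel=1e-12)
            reld = evaluate(parse_expression("D(%)10(cc)"), s, REF).value
            absd = evaluate(parse_expression("D(Gy)10(cc)"), s, REF).value
            assert reld == pytest.approx(absd / REF.value * 100, rel=1e-12)

    def test_rx_ratio_uses_prescription_even_in_maximum_mode(self, linear_dvh):
        max_ref = ReferenceDose("maximum", 80.0)
        mv = evaluate(parse_expression("Dmean/Rx"), linear_dvh, max_ref,
                      rx_dose=50.0)
        assert mv.value == pytest.approx(1.0, rel=1e-12)

    def test_missing_reference_raises(self, linear_dvh):
        with pytest.raises(MissingReferenceError):
            evaluate(parse_expression("D(%)40(cc)"), linear_dvh, None)
        with pytest.raises(MissingReferenceError):
            evaluate(parse_expression("Dmean/Rx"), linear_dvh,
                     ReferenceDose("maximum", 80.0))

    def test_reference_free_expressions_need_no_reference(self, linear_dvh):
        assert evaluate(parse_expression("D(Gy)40(%)"), linear_dvh).value \
            == pytest.approx(60.0)


class TestResolveReferenceDose:
    def test_per_case_rx_overrides_global(self, linear_dvh):
        case = DVHCase("C", (linear_dvh,), rx_dose=60.0)
        ref = resolve_reference_dose(case, RunSettings("prescription", 70.0))
        assert ref.value == 60.0

    def test_global_rx_is_the_fallback(self, linear_dvh):
        case = DVHCase("C", (linear_dvh,))
        ref = resolve_reference_dose(case, RunSettings("prescription", 70.0))
        assert ref.value == 70.0

    def test_maximum_mode_needs_per_case_value(self, linear_dvh):
        case = DVHCase("C", (linear_dvh,), global_max_dose=80.0)
        ref = resolve_reference_dose(case, RunSettings("maximum"))
        assert (ref.mode, ref.value) == ("maximum", 80.0)
        bare = DVHCase("C2", (linear_dvh,))
        with pytest.raises(MissingReferenceError):
            resolve_reference_dose(bare, RunSettings("maximum"))

    def test_prescription_mode_without_any_rx_fails(self, linear_dvh):
        case = DVHCase("C", (linear_dvh,))
        with pytest.raises(MissingReferenceError):
            resolve_reference_dose(case, RunSettings("prescription"))
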