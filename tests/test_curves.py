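"""Component score curves: anchors, monotonicity, continuity, poly export."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from evoo_nvs import (
    CalibrationError,
    eval_curve,
    fit_poly6,
    make_clamped_logistic,
    make_piecewise_linear,
)
from evoo_nvs.curves import TwoBranchLogistic, default_curve_set

WEIGHTS = {
    "oleic": 34.0, "sfa": 5.0, "ratio": 5.0, "phenolics": 26.0,
    "tocopherols": 12.0, "free_acidity": 6.0, "peroxide_value": 6.0,
    "k232": 3.0, "k270": 3.0,
}
CURVES = default_curve_set(WEIGHTS)


class TestClampedLogistic:
    def test_free_acidity_anchors_and_clamp(self):
        curve = CURVES["free_acidity"]
        assert eval_curve(curve, 0.10) == 0.0
        assert eval_curve(curve, 0.05) == 0.0          # clamped below
        assert eval_curve(curve, 0.50) == curve.weight
        assert eval_curve(curve, 0.60) == curve.weight  # clamped above

    def test_midpoint_value_matches_closed_form(self):
        # Independent evaluation of the normalised-logistic closed form.
        curve = CURVES["free_acidity"]
        sig = lambda t: 1.0 / (1.0 + math.exp(-t))
        s0 = sig((0.10 - 0.30) / 0.07)
        s1 = sig((0.50 - 0.30) / 0.07)
        expected = curve.weight * (0.5 - s0) / (s1 - s0)
        assert eval_curve(curve, 0.30) == pytest.approx(expected, abs=1e-12)
        assert 0.0 < expected < curve.weight

    def test_decreasing_orientation(self):
        curve = CURVES["ratio"]
        assert curve.orientation == "decreasing"
        assert eval_curve(curve, 34.0) == 0.0
        assert eval_curve(curve, 40.0) == 0.0
        assert eval_curve(curve, 2.4) == curve.weight
        assert eval_curve(curve, 1.0) == curve.weight

    def test_midpoint_outside_anchors_rejected(self):
        with pytest.raises(CalibrationError, match="midpoint"):
            make_clamped_logistic("bad", 0.1, 0.5, midpoint=0.6, scale=0.1, weight=1.0)

    def test_equal_anchors_rejected(self):
        with pytest.raises(CalibrationError, match="anchors"):
            make_clamped_logistic("bad", 0.5, 0.5, midpoint=0.5, scale=0.1, weight=1.0)

    def test_orientation_contradiction_rejected(self):
        with pytest.raises(CalibrationError, match="orientation"):
            make_clamped_logistic("bad", 0.1, 0.5, midpoint=0.3, scale=0.1,
                                  weight=1.0, orientation="decreasing")


class TestPiecewiseLinear:
    def test_peroxide_knot_values(self):
        curve = CURVES["peroxide_value"]
        w = curve.weight
        assert eval_curve(curve, 3.0) == 0.0
        assert eval_curve(curve, 18.0) == w
        assert eval_curve(curve, 25.0) == w
        # linear interpolation between (6, 0.10) and (10, 0.30)
        assert eval_curve(curve, 8.0) == pytest.approx(0.20 * w, abs=1e-12)

    def test_accelerating_penalty_segments(self):
        # The peroxide deduction's segment slopes strictly increase.
        knots = CURVES["peroxide_value"].knots
        slopes = [
            (f2 - f1) / (x2 - x1)
            for (x1, f1), (x2, f2) in zip(knots, knots[1:])
        ]
        assert all(b > a for a, b in zip(slopes, slopes[1:]))

    def test_tocopherol_breakpoint(self):
        curve = CURVES["tocopherols"]
        assert eval_curve(curve, 250.0) == pytest.approx(0.55 * curve.weight)
        assert eval_curve(curve, 600.0) == curve.weight

    def test_non_monotone_knots_rejected(self):
        with pytest.raises(CalibrationError, match="strictly increase"):
            make_piecewise_linear("bad", [(0, 0), (5, 0.8), (10, 0.5)], weight=1.0)
        with pytest.raises(CalibrationError, match="strictly increase"):
            make_piecewise_linear("bad", [(0, 0), (0, 0.5), (10, 1.0)], weight=1.0)

    def test_too_few_knots_rejected(self):
        with pytest.raises(CalibrationError, match="knots"):
            make_piecewise_linear("bad", [(0, 0.0)], weight=1.0)

    def test_decreasing_orientation_flips_fractions(self):
        curve = make_piecewise_linear(
            "down", [(0, 0.0), (10, 1.0)], weight=4.0, orientation="decreasing"
        )
        assert eval_curve(curve, 0.0) == 4.0
        assert eval_curve(curve, 10.0) == 0.0
        assert curve.anchor_zero == 10.0 and curve.anchor_sat == 0.0


class TestTwoBranchLogistic:
    def test_breakpoint_continuity_and_value(self):
        curve = CURVES["phenolics"]
        w = curve.weight
        assert eval_curve(curve, 250.0) == pytest.approx(0.35 * w, abs=1e-9)
        eps = 1e-9
        assert abs(eval_curve(curve, 250.0 - eps) - eval_curve(curve, 250.0 + eps)) < 1e-6

    def test_small_score_below_health_claim_threshold(self):
        # Oils below 150 mg/kg collect at most 10% of the phenolic weight.
        curve = CURVES["phenolics"]
        assert eval_curve(curve, 150.0) <= 0.10 * curve.weight

    def test_anchors(self):
        curve = CURVES["phenolics"]
        assert eval_curve(curve, 0.0) == 0.0
        assert eval_curve(curve, 800.0) == curve.weight
        assert eval_curve(curve, 1200.0) == curve.weight

    def test_misordered_anchors_rejected(self):
        with pytest.raises(CalibrationError):
            TwoBranchLogistic(
                name="bad", anchor_zero=0.0, breakpoint=900.0, anchor_sat=800.0,
                breakpoint_fraction=0.35, midpoint_low=190.0, scale_low=35.0,
                midpoint_high=500.0, scale_high=90.0, weight=26.0,
            )


@pytest.mark.parametrize("name", sorted(CURVES))
class TestCurveContracts:
    def test_anchor_conformance(self, name):
        curve = CURVES[name]
        assert abs(eval_curve(curve, curve.anchor_zero)) <= 1e-9
        assert abs(eval_curve(curve, curve.anchor_sat) - curve.weight) <= 1e-9

    @given(data=st.data())
    def test_bounded_and_monotone(self, name, data):
        curve = CURVES[name]
        lo, hi = curve.active_interval
        pad = 0.5 * (hi - lo)
        v1 = data.draw(st.floats(lo - pad, hi + pad), label="v1")
        v2 = data.draw(st.floats(v1, hi + pad), label="v2")
        f1, f2 = eval_curve(curve, v1), eval_curve(curve, v2)
        assert -1e-12 <= f1 <= curve.weight + 1e-12
        if getattr(curve, "orientation", "increasing") == "increasing":
            assert f1 <= f2 + 1e-12
        else:
            assert f2 <= f1 + 1e-12

    def test_continuity_at_breakpoints(self, name):
        curve = CURVES[name]
        lo, hi = curve.active_interval
        points = {lo, hi}
        if hasattr(curve, "knots"):
            points |= {k[0] for k in curve.knots}
        if hasattr(curve, "breakpoint"):
            points.add(curve.breakpoint)
        eps = 1e-12
        for p in points:
            jump = abs(eval_curve(curve, p - eps) - eval_curve(curve, p + eps))
            assert jump <= 1e-9, f"{name} jumps by {jump} at {p}"

    def test_vectorised_evaluation_matches_scalar(self, name):
        curve = CURVES[name]
        lo, hi = curve.active_interval
        grid = np.linspace(lo - 1.0, hi + 1.0, 41)
        vec = curve.evaluate(grid)
        assert vec.shape == grid.shape
        assert vec == pytest.approx([eval_curve(curve, v) for v in grid])


class TestPoly6:
    def test_zero_curve_fits_exactly(self):
        curve = make_piecewise_linear("null", [(0, 0.0), (1, 1.0)], weight=0.0)
        spec = fit_poly6(curve, n_grid=50)
        assert spec.max_deviation == 0.0
        for piece in spec.pieces:
            assert all(c == 0.0 for c in piece.coefficients)

    def test_logistic_fit_within_one_percent_on_fresh_grid(self):
        curve = CURVES["free_acidity"]
        spec = fit_poly6(curve, n_grid=200)
        grid = np.linspace(*curve.active_interval, 997)  # independent grid
        dev = np.max(np.abs(spec.evaluate(grid) - curve.evaluate(grid)))
        assert dev < 0.01 * curve.weight

    def test_line_is_reproduced_exactly(self):
        curve = make_piecewise_linear("line", [(2.0, 0.0), (9.0, 1.0)], weight=5.0)
        spec = fit_poly6(curve, n_grid=60)
        assert spec.max_deviation < 1e-8 * curve.weight

    def test_roundtrip_deviation_bound_holds_on_independent_grid(self):
        for name, curve in CURVES.items():
            spec = fit_poly6(curve, n_grid=120)
            for piece in spec.pieces:
                grid = np.linspace(piece.lo, piece.hi, 313)
                dev = np.max(np.abs(piece.evaluate(grid) - curve.evaluate(grid)))
                assert dev <= spec.max_deviation * 1.25 + 1e-12, name

    def test_clamps_outside_active_interval(self):
        curve = CURVES["k232"]
        spec = fit_poly6(curve)
        assert spec.evaluate(0.0) == 0.0
        assert spec.evaluate(5.0) == curve.weight

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(CalibrationError, match="n_grid"):
            fit_poly6(CURVES["k232"], n_grid=13)

    def test_coefficient_order_is_degree6_down_to_constant(self):
        curve = make_piecewise_linear("line", [(0.0, 0.0), (1.0, 1.0)], weight=2.0)
        (piece,) = fit_poly6(curve, n_grid=30).pieces
        # f(v) = 2v on [0, 1]: g (constant) ~ 0, f (linear coefficient) ~ 2
        assert piece.coefficients[-1] == pytest.approx(0.0, abs=1e-9)
        assert piece.coefficients[-2] == pytest.approx(2.0, abs=1e-7)
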