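"""Calibrated component score curves.

Each chemical component contributes a dimensionless score between 0 and its
weight, produced by a monotone curve anchored at two printed boundary values:
the input where the score is exactly 0 and the input where it saturates at
the full weight.  Two families cover every component:

* a *clamped normalised logistic* — a logistic in the input, affinely
  rescaled so the anchors are hit exactly (a raw logistic only approaches its
  asymptotes), and clamped flat beyond them;
* a *piecewise-linear* curve through explicit knots, used where the score
  should change rate abruptly (peroxide value, tocopherols).

The phenolic component is a two-branch logistic: a shallow branch up to the
250 mg/kg health-claim threshold and a steeper branch above it, continuous at
the breakpoint, so oils that qualify for the polyphenol claim collect an
extra premium.

:func:`fit_poly6` exports any curve as piecewise degree-6 polynomials, the
algebraic form in which such score models are conventionally printed.
"""

from __future__ import annotations

from functools import cached_property
from typing import Literal, Mapping, Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit

__all__ = [
    "CalibrationError",
    "ClampedLogistic",
    "PiecewiseLinear",
    "TwoBranchLogistic",
    "Curve",
    "make_clamped_logistic",
    "make_piecewise_linear",
    "eval_curve",
    "Poly6Piece",
    "Poly6Spec",
    "fit_poly6",
    "default_curve_set",
    "curve_from_dict",
    "COMPONENTS",
]


class CalibrationError(Exception):
    """A curve specification is internally inconsistent.

    Deliberately not a ValueError: model validators raise it past pydantic's
    error collection, so callers always see the calibration message directly.
    """


Orientation = Literal["increasing", "decreasing"]


class ClampedLogistic(BaseModel):
    """Normalised logistic between two anchors, clamped outside them.

    ``f(v) = weight * clip((s(v) - s(z0)) / (s(z1) - s(z0)), 0, 1)`` with
    ``s(v) = sigmoid((v - midpoint)/scale)``, ``z0 = anchor_zero`` and
    ``z1 = anchor_sat``.  The normalisation guarantees ``f(z0) = 0`` and
    ``f(z1) = weight`` exactly; ``anchor_sat < anchor_zero`` yields a
    decreasing curve.
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["clamped_logistic"] = "clamped_logistic"
    name: str
    anchor_zero: float
    anchor_sat: float
    midpoint: float
    scale: float = Field(gt=0.0)
    weight: float = Field(ge=0.0)
    orientation: Orientation | None = None

    @model_validator(mode="after")
    def _calibrate(self) -> "ClampedLogistic":
        if self.anchor_zero == self.anchor_sat:
            raise CalibrationError(f"{self.name}: anchors must differ")
        lo, hi = sorted((self.anchor_zero, self.anchor_sat))
        if not lo < self.midpoint < hi:
            raise CalibrationError(
                f"{self.name}: midpoint {self.midpoint} outside open anchor "
                f"interval ({lo}, {hi})"
            )
        derived: Orientation = (
            "increasing" if self.anchor_sat > self.anchor_zero else "decreasing"
        )
        if self.orientation is None:
            object.__setattr__(self, "orientation", derived)
        elif self.orientation != derived:
            raise CalibrationError(
                f"{self.name}: orientation {self.orientation!r} contradicts anchors"
            )
        return self

    @property
    def active_interval(self) -> tuple[float, float]:
        return tuple(sorted((self.anchor_zero, self.anchor_sat)))

    @cached_property
    def _norm(self) -> tuple[float, float]:
        s0 = expit((self.anchor_zero - self.midpoint) / self.scale)
        s1 = expit((self.anchor_sat - self.midpoint) / self.scale)
        return float(s0), float(s1)

    def evaluate(self, v):
        s0, s1 = self._norm
        s = expit((np.asarray(v, dtype=float) - self.midpoint) / self.scale)
        frac = np.clip((s - s0) / (s1 - s0), 0.0, 1.0)
        return self.weight * frac

    def smooth_pieces(self) -> list[tuple[float, float]]:
        return [self.active_interval]


class PiecewiseLinear(BaseModel):
    """Continuous piecewise-linear curve through ``(input, fraction)`` knots.

    Fractions run strictly from 0 to 1; the score is ``weight * fraction``,
    clamped flat outside the first and last knots.
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["piecewise_linear"] = "piecewise_linear"
    name: str
    knots: tuple[tuple[float, float], ...]
    weight: float = Field(ge=0.0)
    orientation: Orientation = "increasing"

    @model_validator(mode="after")
    def _calibrate(self) -> "PiecewiseLinear":
        if len(self.knots) < 2:
            raise CalibrationError(f"{self.name}: at least 2 knots required")
        xs = [k[0] for k in self.knots]
        fr = [k[1] for k in self.knots]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise CalibrationError(f"{self.name}: knot inputs must strictly increase")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise CalibrationError(f"{self.name}: knot fractions must strictly increase")
        if fr[0] != 0.0 or fr[-1] != 1.0:
            raise CalibrationError(f"{self.name}: knot fractions must run from 0 to 1")
        return self

    @property
    def active_interval(self) -> tuple[float, float]:
        return (self.knots[0][0], self.knots[-1][0])

    @property
    def anchor_zero(self) -> float:
        return self.knots[0][0] if self.orientation == "increasing" else self.knots[-1][0]

    @property
    def anchor_sat(self) -> float:
        return self.knots[-1][0] if self.orientation == "increasing" else self.knots[0][0]

    def evaluate(self, v):
        xs = np.array([k[0] for k in self.knots])
        fr = np.array([k[1] for k in self.knots])
        frac = np.interp(np.asarray(v, dtype=float), xs, fr)
        if self.orientation == "decreasing":
            frac = 1.0 - frac
        return self.weight * frac

    def smooth_pieces(self) -> list[tuple[float, float]]:
        xs = [k[0] for k in self.knots]
        return list(zip(xs, xs[1:]))


class TwoBranchLogistic(BaseModel):
    """Increasing curve made of two normalised logistics joined at a breakpoint.

    The low branch rises from 0 at ``anchor_zero`` to
    ``breakpoint_fraction * weight`` at ``breakpoint``; the high branch
    continues to the full weight at ``anchor_sat``.  Continuity at the
    breakpoint is structural: the low branch saturates there exactly where
    the high branch starts from zero.
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["two_branch_logistic"] = "two_branch_logistic"
    name: str
    anchor_zero: float
    breakpoint: float
    anchor_sat: float
    breakpoint_fraction: float = Field(gt=0.0, lt=1.0)
    midpoint_low: float
    scale_low: float = Field(gt=0.0)
    midpoint_high: float
    scale_high: float = Field(gt=0.0)
    weight: float = Field(ge=0.0)
    orientation: Literal["increasing"] = "increasing"

    @model_validator(mode="after")
    def _calibrate(self) -> "TwoBranchLogistic":
        if not self.anchor_zero < self.breakpoint < self.anchor_sat:
            raise CalibrationError(
                f"{self.name}: anchors must satisfy anchor_zero < breakpoint < anchor_sat"
            )
        # Branch construction re-runs the ClampedLogistic validators.
        self._branches  # noqa: B018
        return self

    @cached_property
    def _branches(self) -> tuple[ClampedLogistic, ClampedLogistic]:
        low = ClampedLogistic(
            name=f"{self.name}[low]",
            anchor_zero=self.anchor_zero,
            anchor_sat=self.breakpoint,
            midpoint=self.midpoint_low,
            scale=self.scale_low,
            weight=self.breakpoint_fraction * self.weight,
        )
        high = ClampedLogistic(
            name=f"{self.name}[high]",
            anchor_zero=self.breakpoint,
            anchor_sat=self.anchor_sat,
            midpoint=self.midpoint_high,
            scale=self.scale_high,
            weight=(1.0 - self.breakpoint_fraction) * self.weight,
        )
        return low, high

    @property
    def active_interval(self) -> tuple[float, float]:
        return (self.anchor_zero, self.anchor_sat)

    def evaluate(self, v):
        low, high = self._branches
        return low.evaluate(v) + high.evaluate(v)

    def smooth_pieces(self) -> list[tuple[float, float]]:
        return [(self.anchor_zero, self.breakpoint), (self.breakpoint, self.anchor_sat)]


Curve = Union[ClampedLogistic, PiecewiseLinear, TwoBranchLogistic]


def make_clamped_logistic(
    name: str,
    anchor_zero: float,
    anchor_sat: float,
    midpoint: float,
    scale: float,
    weight: float,
    orientation: Orientation | None = None,
) -> ClampedLogistic:
    return ClampedLogistic(
        name=name,
        anchor_zero=anchor_zero,
        anchor_sat=anchor_sat,
        midpoint=midpoint,
        scale=scale,
        weight=weight,
        orientation=orientation,
    )


def make_piecewise_linear(
    name: str,
    knots: Sequence[tuple[float, float]],
    weight: float,
    orientation: Orientation = "increasing",
) -> PiecewiseLinear:
    return PiecewiseLinear(
        name=name, knots=tuple(tuple(k) for k in knots), weight=weight,
        orientation=orientation,
    )


def eval_curve(curve: Curve, v):
    """Evaluate a curve at scalar or array input; scalars come back as float."""
    out = curve.evaluate(v)
    if np.ndim(v) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Degree-6 polynomial export


class Poly6Piece(BaseModel):
    """One polynomial piece: coefficients a..g (degree 6 down to constant)."""

    model_config = ConfigDict(frozen=True)

    lo: float
    hi: float
    coefficients: tuple[float, float, float, float, float, float, float]

    def evaluate(self, v):
        return np.polyval(self.coefficients, np.asarray(v, dtype=float))


class Poly6Spec(BaseModel):
    """Piecewise degree-6 polynomial representation of a score curve.

    Curves with interior knots or branch points get one coefficient set per
    smooth piece, mirroring how multi-branch score models are printed (one
    equation per branch).  Outside the active interval the polynomial is
    clamped to the curve's endpoint values.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    pieces: tuple[Poly6Piece, ...]
    clamp_low: float
    clamp_high: float
    max_deviation: float

    @property
    def active_interval(self) -> tuple[float, float]:
        return (self.pieces[0].lo, self.pieces[-1].hi)

    def evaluate(self, v):
        x = np.asarray(v, dtype=float)
        lo, hi = self.active_interval
        out = np.where(x < lo, self.clamp_low, np.where(x > hi, self.clamp_high, 0.0))
        inside = (x >= lo) & (x <= hi)
        for piece in self.pieces:
            mask = inside & (x >= piece.lo) & (x <= piece.hi)
            if mask.any():
                out = np.where(mask, piece.evaluate(x), out)
        if np.ndim(v) == 0:
            return float(out)
        return out


def _fit_piece(curve: Curve, lo: float, hi: float, n_grid: int) -> Poly6Piece:
    """Minimax-oriented degree-6 fit on an equispaced grid over ``[lo, hi]``.

    Plain least squares concentrates its worst error near the steep anchor
    regions; Lawson's iteratively reweighted least squares drives the fit
    toward the uniform-error (minimax) polynomial instead, which is what the
    printed-parity check measures.  The fit runs in a Chebyshev basis for
    conditioning and is converted exactly to power-basis coefficients.
    """
    if not hi > lo:
        raise CalibrationError(f"{curve.name}: degenerate interval [{lo}, {hi}]")
    deg = 6
    grid = np.linspace(lo, hi, n_grid)
    t = (2.0 * grid - lo - hi) / (hi - lo)
    design = np.polynomial.chebyshev.chebvander(t, deg)
    y = np.asarray(curve.evaluate(grid), dtype=float)
    w = np.full(n_grid, 1.0 / n_grid)
    coef = np.zeros(deg + 1)
    for _ in range(80):
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        resid = np.abs(design @ coef - y)
        w = w * (resid + 1e-15)
        total = w.sum()
        if total <= 0.0:
            break
        w /= total
    cheb = np.polynomial.Chebyshev(coef, domain=[lo, hi])
    power = cheb.convert(domain=[lo, hi], kind=np.polynomial.Polynomial, window=[lo, hi])
    asc = np.zeros(deg + 1)
    asc[: len(power.coef)] = power.coef
    desc = tuple(float(c) for c in asc[::-1])
    return Poly6Piece(lo=lo, hi=hi, coefficients=desc)


def fit_poly6(curve: Curve, n_grid: int = 200) -> Poly6Spec:
    """Fit piecewise degree-6 polynomials to a curve over its smooth pieces.

    ``n_grid`` (>= 14, twice the coefficient count) is the number of
    equispaced fit points per piece.  The reported ``max_deviation`` is
    measured on a fresh, four-times-denser grid.
    """
    if n_grid < 14:
        raise CalibrationError("n_grid must be at least 14 (two times the coefficient count)")
    pieces = [_fit_piece(curve, lo, hi, n_grid) for lo, hi in curve.smooth_pieces()]
    dev = 0.0
    for piece in pieces:
        check = np.linspace(piece.lo, piece.hi, 4 * n_grid + 1)
        dev = max(dev, float(np.max(np.abs(piece.evaluate(check) - curve.evaluate(check)))))
    lo, hi = curve.active_interval
    return Poly6Spec(
        name=curve.name,
        pieces=tuple(pieces),
        clamp_low=float(curve.evaluate(lo)),
        clamp_high=float(curve.evaluate(hi)),
        max_deviation=dev,
    )


# ---------------------------------------------------------------------------
# Default calibration

#: Component keys, in reporting order.
COMPONENTS: tuple[str, ...] = (
    "oleic",
    "sfa",
    "ratio",
    "phenolics",
    "tocopherols",
    "free_acidity",
    "peroxide_value",
    "k232",
    "k270",
)


def default_curve_set(weights: Mapping[str, float]) -> dict[str, Curve]:
    """The packaged default calibration, one curve per component.

    Anchors come from the printed boundary conditions (score 0 / full weight
    at the stated inputs); midpoints and scales place each curve's steep
    region over the densest part of the corresponding reference
    distribution.  ``weights`` maps component key to its maximum score.
    """
    w = dict(weights)
    missing = set(COMPONENTS) - set(w)
    if missing:
        raise CalibrationError(f"missing weights for components: {sorted(missing)}")
    return {
        "oleic": make_clamped_logistic(
            "oleic", anchor_zero=55.0, anchor_sat=85.0, midpoint=71.0, scale=4.0,
            weight=w["oleic"],
        ),
        "sfa": make_clamped_logistic(
            "sfa", anchor_zero=7.5, anchor_sat=25.0, midpoint=16.0, scale=2.5,
            weight=w["sfa"],
        ),
        "ratio": make_clamped_logistic(
            "ratio", anchor_zero=34.0, anchor_sat=2.4, midpoint=8.0, scale=3.0,
            weight=w["ratio"],
        ),
        "phenolics": TwoBranchLogistic(
            name="phenolics", anchor_zero=0.0, breakpoint=250.0, anchor_sat=800.0,
            breakpoint_fraction=0.35, midpoint_low=190.0, scale_low=35.0,
            midpoint_high=500.0, scale_high=90.0, weight=w["phenolics"],
        ),
        "tocopherols": make_piecewise_linear(
            "tocopherols", [(0.0, 0.0), (250.0, 0.55), (500.0, 1.0)],
            weight=w["tocopherols"],
        ),
        "free_acidity": make_clamped_logistic(
            "free_acidity", anchor_zero=0.10, anchor_sat=0.50, midpoint=0.30,
            scale=0.07, weight=w["free_acidity"],
        ),
        "peroxide_value": make_piecewise_linear(
            "peroxide_value", [(3.0, 0.0), (6.0, 0.10), (10.0, 0.30), (18.0, 1.0)],
            weight=w["peroxide_value"],
        ),
        "k232": make_clamped_logistic(
            "k232", anchor_zero=1.50, anchor_sat=2.45, midpoint=1.95, scale=0.15,
            weight=w["k232"],
        ),
        "k270": make_clamped_logistic(
            "k270", anchor_zero=0.10, anchor_sat=0.20, midpoint=0.15, scale=0.02,
            weight=w["k270"],
        ),
    }


def curve_from_dict(name: str, spec: Mapping) -> Curve:
    """Build a curve from a config-file mapping (``kind`` selects the family)."""
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind == "clamped_logistic":
        return ClampedLogistic(name=name, **spec)
    if kind == "piecewise_linear":
        knots = tuple(tuple(k) for k in spec.pop("knots"))
        return PiecewiseLinear(name=name, knots=knots, **spec)
    if kind == "two_branch_logistic":
        return TwoBranchLogistic(name=name, **spec)
    raise CalibrationError(f"{name}: unknown curve kind {kind!r}")
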