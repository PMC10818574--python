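# Methods

## The score in one paragraph

`evoo-nvs` ranks the nutritional value of extra virgin olive oil (EVOO) on a
0–100 scale. Scoring is gated: a sample must first conform to every EVOO
legal chemical limit (and, when sensory medians are supplied, the sensory
limits), otherwise it is excluded and no score is produced. For conforming
samples the score is

```
NVS = K + (X_PC1 + Y_PC2 + Z_PC3) − (X_NC1 + Y_NC2 + Z_NC3)
X_PC1 = X_OA − X_SFA − X_Rat          Z_NC3 = Z_K232 + Z_K270
```

Positive components: fatty-acid composition (oleic-acid score minus
saturated-fat and oxidative-stability-ratio deductions), total hydrophilic
phenolics, and total tocopherols. Negative components: free acidity,
peroxide value, and the UV extinction indices K232/K270. Each elementary
term is a monotone curve of one measured quantity, bounded between 0 and a
component weight.

## The conformity gate

Legal limits are a versioned data table (`data/legal_limits.yaml`, version
`eu-2022`), not code: EU limits are revised periodically and panels may need
to be re-evaluated under a different version. All intervals are closed —
a free acidity of exactly 0.80 % still conforms. Two modes:

* **lenient** (default): parameters absent from the input (ΔK, trace fatty
  acids, sensory medians) are recorded as skipped. This matches routine
  chemical-only panels.
* **strict**: a missing ΔK or missing sensory median is itself a
  "missing data" violation.

ΔK has no commonly printed limit in the summary sources for the other
indices; the packaged default is |ΔK| ≤ 0.01 (the standard EU value), and it
is only checked when reported. ΔK may be negative — the one field exempt
from the non-negativity validation, because laboratories legitimately report
small negative differences.

The fatty-acid closure check (sum of a *complete* 15-acid profile within
[97, 101] %) emits a warning, never a gate violation: panels routinely omit
trace acids, and closure failure signals a reporting problem rather than a
non-EVOO oil.

The saturated-fat range used by the deduction curve is the limit-derived
[7.5, 25] % (palmitic 7.00–20.00 plus stearic 0.50–5.00).

## Curve families and the default calibration

Only the boundary conditions of the component models are published (where
each score is exactly 0 and where it saturates); the fitted coefficients are
not. The package therefore defines each curve by its anchors plus a small
number of shape parameters, all overridable through the run configuration.

**Clamped normalised logistic.** `f(v) = W · clip((σ(t(v)) − σ(t0)) /
(σ(t1) − σ(t0)), 0, 1)` with `t(v) = (v − midpoint)/scale`. The affine
normalisation makes the anchors exact (a raw logistic only approaches 0 and
W asymptotically); clamping keeps the curve flat beyond them. Swapping the
anchors yields a decreasing curve with no extra machinery.

**Piecewise linear.** Knots `(input, fraction-of-weight)` with fractions
strictly increasing 0 → 1, clamped outside; used where the rate of change
should switch abruptly.

**Two-branch logistic (phenolics).** Two normalised logistics joined at the
250 mg/kg threshold — the EFSA "olive oil polyphenols" health-claim level —
carrying 35 % of the weight below it and 65 % above. Continuity at the
junction is structural (the low branch saturates exactly where the high
branch starts at zero). Oils under 150 mg/kg collect at most 10 % of the
phenolic weight; the premium above 250 mg/kg implements the "extra score"
for claim-qualifying oils.

Default parameters (anchors from the published boundary conditions;
midpoints/scales chosen so each curve's steep region covers the densest bins
of the reference distributions):

| component | kind | anchors (0 → W) | shape | rationale for the steep region |
|---|---|---|---|---|
| oleic (%) | logistic | 55 → 85 | mid 71, scale 4 | most cohorts sit above 71 % |
| SFA deduction (%) | logistic | 7.5 → 25 | mid 16, scale 2.5 | bulk of oils in 11–20 % |
| ratio deduction | logistic | 34 → 2.4 (decreasing) | mid 8, scale 3 | bulk of oils in 7–14 |
| phenolics (mg/kg) | two-branch | 0 → 800, break 250 | mids 190/500, scales 35/90 | mass in 250–500; >800 is ≤0.7 % of oils |
| tocopherols (mg/kg) | piecewise | 0 → 500 | knot (250, 0.55) | steeper first segment discriminates the common 100–300 range |
| free acidity (%) | logistic | 0.10 → 0.50 | mid 0.30, scale 0.07 | mass in 0.15–0.40 |
| peroxide value (meq O₂/kg) | piecewise | 3 → 18 | knots (6, 0.10), (10, 0.30) | three segments with strictly increasing slopes: an accelerating penalty |
| K232 | logistic | 1.50 → 2.45 | mid 1.95, scale 0.15 | mass in 1.65–2.15 |
| K270 | logistic | 0.10 → 0.20 | mid 0.15, scale 0.02 | mass in 0.13–0.17 |

The sigmoid family itself is a design choice — only the sigmoidal character
of the component models is fixed, not the family — and the logistic was
chosen for its standard shape and cheap, stable evaluation. The two
piecewise curves bend in opposite directions by design: an accelerating
(convex) penalty for peroxide value, and a steeper-first (concave) reward
for tocopherols so the common 100–300 mg/kg range is discriminated. The
tocopherol model uses two linear segments rather than a single line for the
same discrimination reason.

## The weight budget

Weights live in configuration; the packaged defaults are
34 / 5 / 5 / 26 / 12 (oleic, SFA, ratio, phenolics, tocopherols) and
6 / 6 / 3+3 (free acidity, peroxide value, K232+K270), with K = 28. They are
one admissible solution of the qualitative constraints — oleic largest
single positive weight; fatty-acid block and phenolics each at least the
tocopherol weight; the three negative components with equal maxima, the UV
penalty split equally between the two indices — plus the two pinning
identities

```
P_max − P_min + N_max = 100        K = N_max − P_min
```

(P_max = 34+26+12 = 72, P_min = −10, N_max = 18), which make the
component-wise worst combination score exactly 0 and the best exactly 100.
`check_weight_budget` verifies all of this to 1e−9 and reports each failed
constraint by name. The extreme endpoints are *component-wise*: a single
real oil cannot hold SFA = 25 % and ratio = 2.4 simultaneously under
compositional closure, so feasible scores span a narrower interior range
(synthetic realistic cohorts land roughly in 30–92). Clamping of the final
score to [0, 100] exists purely as numerical insurance; with any
budget-valid configuration it never triggers, and the result flags it if it
ever does.

## Polynomial export

`fit_poly6` renders any curve as piecewise degree-6 polynomials, the
algebraic form in which such score models are conventionally printed. Fits
are per smooth piece — per linear segment and per logistic branch — so
multi-branch components get one coefficient set per branch, matching the
printed convention. Each piece is fitted on an equispaced grid (default 200
points, minimum 14 = twice the coefficient count) by Lawson's iteratively
reweighted least squares, which converges toward the minimax (uniform-error)
polynomial; plain least squares was rejected because it concentrates error
at the steep anchor ends and exceeded 1 % of weight on the long-tailed ratio
curve (1.8 % vs 0.7 % for the IRLS fit). The fit runs in a Chebyshev basis
for conditioning and is converted exactly to power-basis coefficients
(degree 6 down to the constant). The reported `max_deviation` is measured
on a fresh grid four times denser than the fit grid. All nine default
curves fit within 1 % of their weight; linear segments are reproduced to
machine precision.

## The synthetic cohort generator

The generator emulates the study cohorts behind the calibration — the 2013
harvest (no olive-fly pressure), the 2014 harvest (strong olive-fly attack),
commercial bottlings, and six countries of origin — from their printed
binned marginals, since the underlying per-sample data are unpublished.

* **Independent parameters** (free acidity, peroxide value, K232, K270,
  phenolics, tocopherols) are drawn by inverse-CDF from the cohort histogram
  *conditioned on the legal box*: bins wholly outside a legal limit are
  dropped and the rest renormalised. This realises exactly the same law as
  rejection-resampling out-of-limit draws, at deterministic cost. Within a
  bin the law is uniform; open-ended top bins get an exponential tail with
  scale equal to half the width of the last closed bin.
* **Fatty acids** are generated under compositional closure: draw oleic,
  linoleic, SFA (split palmitic:stearic = 0.85:0.15, with the SFA support
  truncated to the split-feasible [8.24, 23.53] %) and linolenic uniform on
  [0.3, 0.9] % (no marginal is published for linolenic; this sits inside its
  < 1.00 % limit). The remainder to 100 % must fit palmitoleic (legal
  0.30–3.50 %) plus a small unnamed trace-acid slack, i.e. lie in
  [0.3, 4.5] %; infeasible draws are rejected and redrawn. Acceptance rates
  are 22–43 % across all nine cohorts; a profile rejecting more than 99 % of
  draws raises an error.
* **Dependence** is off by default (only marginals are published). An
  optional Gaussian copula couples oleic and linoleic at rank correlation
  −0.6, approximating their opposing patterns across origins. The stability
  ratio is always computed from the drawn acids, never sampled, so its
  reference table is an emergent check rather than a calibration target.

Cohorts lacking their own tables borrow, and the profile flags every
substitution: commercial phenolics/tocopherols use the two year histograms
pooled with the study sample counts (564:605 and 464:397); origin cohorts
additionally borrow the commercial quality-index histograms.

**What passing tests do and do not show.** Generated panels pass the gate by
construction, and the independently drawn parameters recover their
conditioned reference marginals to within multinomial sampling error
(checked at n = 5000, three standard errors per bin). The closure
constraint, however, necessarily reshapes the fatty-acid marginals relative
to the printed columns — independent printed marginals and closure are
jointly infeasible — so oleic/linoleic/SFA are checked for reproducibility
of the generator's own law (two independent runs), not against the printed
columns. Synthetic cohorts also carry no real inter-parameter correlations
beyond the optional copula, no storage-time structure, and no sensory data.
Conclusions from synthetic panels therefore validate the scoring pipeline's
behaviour, not field prevalence of any score range.

## Numerical choices

* Anchor exactness: the normalised logistic hits 0 and W exactly in floating
  point; tests require ≤ 1e−9.
* Continuity: the score is continuous in every input; tests probe every
  anchor, knot and the 250 mg/kg branch point with ε = 1e−12 and require
  jumps ≤ 1e−9.
* CSV round trips are bit-exact: floats are written with `%.17g` and parsed
  with pandas' `round_trip` parser.
* Determinism: all generator randomness flows through one seeded
  `numpy.random.Generator`; identical (profile, n, seed) give identical
  panels, and scoring the same panel twice is bit-identical.
* Degenerate inputs: a zero polyunsaturated load (linoleic + 2·linolenic =
  0) makes the stability ratio undefined and raises; it cannot occur inside
  the legal box (linoleic ≥ 2.5 %).
* Sensory defect median must equal zero to an absolute 1e−12; fruity median
  must be strictly positive.

## Problem sizes in the shipped tests

Marginal-recovery and score-distribution checks run at n = 5000 per cohort
for the three fully tabulated cohorts; monotonicity uses 10 800 randomised
ordered pairs (1200 per input direction across nine inputs); the range check
draws 10 000 random budget-valid weight configurations with one random
conforming sample each. The whole suite completes in well under a minute on
a laptop-class core.

## Known limitations

* The original fitted component coefficients are not available; this
  package's curves satisfy the same boundary conditions and qualitative
  shape constraints but are not numerically identical to any external
  calibration, so absolute scores are comparable only within one
  configuration (pin it when comparing oils).
* The reference tables carry their printed rounding: integer-printed columns
  can sum to 99–101, and a handful of running-text percentages disagree with
  the tables by up to 0.5 points; the tables are treated as authoritative
  and the discrepancies are asserted in the test suite as documented
  exceptions.
* Gate coverage is limited to the printed limit list: sterol content and
  other purity parameters are out of scope.
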