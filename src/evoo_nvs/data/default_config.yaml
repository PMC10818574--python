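# Packaged default run configuration: weight budget, component score curves,
# gate mode.  The curve weights must equal the corresponding entries of the
# weight budget; this is cross-checked at load time.
weights:
  oleic: 34.0
  sfa: 5.0
  ratio: 5.0
  phenolics: 26.0
  tocopherols: 12.0
  free_acidity: 6.0
  peroxide_value: 6.0
  k232: 3.0
  k270: 3.0
  k_constant: 28.0
curves:
  oleic:
    kind: clamped_logistic
    anchor_zero: 55.0
    anchor_sat: 85.0
    midpoint: 71.0
    scale: 4.0
    weight: 34.0
    orientation: increasing
  sfa:
    kind: clamped_logistic
    anchor_zero: 7.5
    anchor_sat: 25.0
    midpoint: 16.0
    scale: 2.5
    weight: 5.0
    orientation: increasing
  ratio:
    kind: clamped_logistic
    anchor_zero: 34.0
    anchor_sat: 2.4
    midpoint: 8.0
    scale: 3.0
    weight: 5.0
    orientation: decreasing
  phenolics:
    kind: two_branch_logistic
    anchor_zero: 0.0
    breakpoint: 250.0
    anchor_sat: 800.0
    breakpoint_fraction: 0.35
    midpoint_low: 190.0
    scale_low: 35.0
    midpoint_high: 500.0
    scale_high: 90.0
    weight: 26.0
  tocopherols:
    kind: piecewise_linear
    knots: [[0.0, 0.0], [250.0, 0.55], [500.0, 1.0]]
    weight: 12.0
    orientation: increasing
  free_acidity:
    kind: clamped_logistic
    anchor_zero: 0.10
    anchor_sat: 0.50
    midpoint: 0.30
    scale: 0.07
    weight: 6.0
    orientation: increasing
  peroxide_value:
    kind: piecewise_linear
    knots: [[3.0, 0.0], [6.0, 0.10], [10.0, 0.30], [18.0, 1.0]]
    weight: 6.0
    orientation: increasing
  k232:
    kind: clamped_logistic
    anchor_zero: 1.50
    anchor_sat: 2.45
    midpoint: 1.95
    scale: 0.15
    weight: 3.0
    orientation: increasing
  k270:
    kind: clamped_logistic
    anchor_zero: 0.10
    anchor_sat: 0.20
    midpoint: 0.15
    scale: 0.02
    weight: 3.0
    orientation: increasing
gate:
  mode: lenient
  limits_version: eu-2022
seed: 0
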