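# EU legal limits for the extra virgin olive oil (EVOO) commercial category.
# Each entry is a closed interval [low, high]; a sample conforms when every
# checked parameter lies inside its interval (boundary values conform).
# Limits do change over time, hence the version tag.
version: eu-2022
limits:
  free_acidity: [0.0, 0.80]        # % oleic acid
  peroxide_value: [0.0, 20.0]      # meq O2 / kg oil
  k232: [0.0, 2.50]
  k270: [0.0, 0.22]
  delta_k: [-0.01, 0.01]           # checked only when reported
  myristic: [0.0, 0.03]            # all fatty acids in % of total fatty acids
  palmitic: [7.00, 20.00]
  palmitoleic: [0.30, 3.50]
  margaric: [0.0, 0.40]
  margaroleic: [0.0, 0.60]
  stearic: [0.50, 5.00]
  oleic: [55.00, 85.00]
  linoleic: [2.50, 21.00]
  linolenic: [0.0, 1.00]
  arachidic: [0.0, 0.60]
  eicosenoic: [0.0, 0.50]
  behenic: [0.0, 0.20]
  lignoceric: [0.0, 0.20]
  trans_c18_1: [0.0, 0.05]
  trans_c18_2_3: [0.0, 0.05]
sensory:
  # EVOO sensory gate: fruity median strictly positive, defect median exactly zero.
  fruity_median_min_exclusive: 0.0
  defect_median_exact: 0.0
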