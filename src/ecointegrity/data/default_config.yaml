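# Default pipeline configuration: a synthetic landscape at the study scale
# (140 sites on a 100x100 grid of 500 m pixels) run through scenario b.
seed: 0
output_dir: out
scenario: b
grid:
  origin_x: 0.0
  origin_y: 0.0
  pixel_size: 500.0
  ncols: 100
  nrows: 100
simulation:
  n_sites: 140
  beta0: 0.738
  beta:
    human_settlements: -0.165
    roads: -0.121
    oil_activities: -0.136
    elevation: -0.176
    slope: 0.199
  sigma: null          # null => calibrated to target_r2
  target_r2: 0.25
selection:
  max_terms: null      # null => 7 for scenarios a/b, 2 for c/d
  collinearity_threshold: 0.7
cv:
  k: 7
  repeats: 20
  seed: 7
moran:
  scheme: inverse_distance
  row_standardize: false
microbasins:
  nx: 7
  ny: 7
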