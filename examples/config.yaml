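# Example run configuration (all sections optional; these are the defaults).
seed: 1
pump:
  capacity_ml: 10.0          # disposable 10-mL syringe
  steps_per_ml: 800
  max_rate_ml_min: 10.0
  default_rate_ml_min: 2.0
channels:
  W1: well
  W2: well
  W3: well
  W4: well
  W5: well
  W6: well
  FRESH: fresh-media
  WASTE: waste
sensor:
  slope: -57.7               # green intensity counts per pH unit
  intercept: 1032.0
  ph_low: 6.90               # calibration validity window
  ph_high: 7.83
  noise_sd: 2.0              # counts
  quantize_10bit: false
twin:
  r_per_h: 0.035
  K_cells: 1.2e6
  q_acid_per_cell_h: 3.0e-7
  beta: 3.0
  fresh_ph: 7.45
  ph_optimum: 7.4
  ph_tolerance: 0.2
  seed_cells: 7.0e4
  well_volume_ml: 5.0
sim:
  max_steps: 100000
  dt_max_h: 0.1
  reservoir_ml: 500.0
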