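# Example run configuration for the ffvpsim pipeline.
#
# A 1:10-scale cohort with the study's joint (ever-desert x ever-FFVP)
# proportions, simulated over the standard 180-day x 7-year schedule at the
# calibrated model defaults.

seed: 1
output_dir: ffvpsim_out
log_level: INFO

cohort:
  cell_counts:
    never_desert_never_ffvp: 794
    never_desert_ffvp: 259
    desert_never_ffvp: 1760
    desert_ffvp: 785
  desert_flip_prob: 0.05
  initial_desert_prob: 0.90
  alpha: {family: constant, value: 0.005}

simulation:
  days_per_year: 180
  n_years: 7
  record_every: 60
  # env defaults: p1=0.10, p2=0.35, a=0.1635 (calibrated); lam defaults to 3.0

calibration:
  target: {one_year_effect: 0.3333, tolerance: 0.05, n_rep: 2000}
  space: {a_range: [0.05, 0.6], n_grid: 6, n_refine: 3}

reporting:
  patterns: ["1000000", "0000001", "1110000"]
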