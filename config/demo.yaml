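# Small end-to-end demo: simulate, fit, validate, one resolution experiment.
schema_version: 1
seed: 1
outdir: results/demo
domain:
  n_east_cells: 20
  n_north_cells: 48
  cell_size: [2.8, 3.7]
simulation:
  n_years: 6
  stations_per_year: 150
  n_sim_knots: 80
model:
  include_depth: true
  st_mode: none
  n_knots: 25
  n_starts: 1
  maxiter: 150
experiments:
  run: [resolution]
  factors: [4]
  n_draws: 100
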