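# Demo synthetic study: small enough to run in well under a minute,
# large enough for the paired cluster inference to be meaningful
# (9 pairs -> 512 exact sign flips, minimum cluster p ~ 0.002).
seed: 7
outdir: lagflow_demo_out
log_level: INFO
phantom:
  grid_shape: [16, 16, 8]
  tr: 2.0
  n_volumes: 100
  slfo_band: [0.008, 0.07]
  noise_sd: 0.5
  voxel_size_mm: 3.0
  delay_span: 4.0
  tap_shift: -2.5
  age_slope: 0.05
cohort:
  n_pairs: 9
  n_controls: 14
  age_range: [20.0, 80.0]
  jitter_sd: 0.5
preprocess:
  discard_s: 10.0
  trans_thresh: 3.0
  rot_thresh: 3.0
  rate_window: 0.5
  band: [0.008, 0.07]
  dt: 0.5
lagmap:
  max_lag: 7.0
  step: 0.5
  qc_zero_frac: 0.6
stats:
  fwhm_mm: 6.0
  height_p: 0.005
  cluster_p: 0.005
  n_perm: 2000
  fdr_q: 0.05
  min_cluster_mm3: 540.0   # 20 voxels at 3 mm iso; demo-scale regions are small
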