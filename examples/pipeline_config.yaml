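# Full pipeline configuration with defaults.  Every analysis threshold
# the method leaves open is surfaced here.
out_dir: ctdi_out
traces_dir: null          # default: <out_dir>/traces
metadata_path: null       # default: <out_dir>/metadata.csv
reference_path: null      # default: packaged synthetic reference curves
quality_min: 0.6          # consensus correlation below which a beat is excluded
fusion_prominence: 0.10   # trough prominence separating E from A (fraction)
snr_min: 3.0              # min peak amplitude / noise floor for Am & Em
outlier_z_threshold: 4.0  # |z| audit threshold
first_iut_only: false
cross_segment: true
seed: 0
cohort:                   # synthetic-cohort generator settings
  n_fetuses: 32
  ga_range: [20.0, 36.0]
  hb_mom_range: [0.30, 1.10]
  slope_em_z_per_mom: 1.5
  post_iut_delta_z: {Am: -0.6, Sm: -0.7, Em: -0.35}
  hr_before_mean: 140.4
  hr_before_sd: 9.1
  hr_after_mean: 132.7
  hr_after_sd: 14.4
  residual_z_sd: 1.0
  duration: 4.0
  noise_sd: 0.25
  beat_jitter_cv: 0.02
  p_apical: 0.43
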