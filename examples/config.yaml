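# Example study configuration for `fdgquant run --config examples/config.yaml --out out/`.
# Every key is optional; omitted keys use the package defaults documented in
# docs/methods.md.
design:
  n_subjects: 6
  n_sessions: 2
  sigma_inter: 0.05        # between-subject effect on Ki, log scale
  sigma_intra: 0.18        # global session effect, log scale
  sigma_region: 0.06       # per-region session residual, log scale
  global_scale_cv: 0.145   # plasma-exposure jitter per session
  noise_cv: 0.05           # frame noise CV on the longest frame
  glycemia_mean: 4.5       # mmol/L
  glycemia_sd: 0.7
  dose_mean_mbq: 169.2
  weight_mean_kg: 5.8
  rng_seed: 1234
  # region_ki_map: {pons: 0.0119, cerebellum: 0.0159, ...}
  # frame_durations: [[4, 15], [4, 30], [2, 60], [5, 120], [3, 300], [9, 600]]
  # frame_max_end_s: 3600
quantification:
  lumped_constant: 0.34
  t_star_min: 30.0
  plateau_window_min: [30.0, 60.0]
  reference_regions: [pons, cerebellum]
  glycemia_source: arterial
robustness:
  n_subjects: 4
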