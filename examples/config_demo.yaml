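# Two-condition demo configuration for `pmspt run --config`.
seed: 21
out_dir: pmspt_demo_run
conditions:
  - label: CK
    tirf:
      field_size_px: [96, 96]
      n_frames: 150
      diffusion_um2_s: 2.0e-3
      dwell_mean_s: 2.0
      birth_rate_per_frame: 1.0
  - label: MeJA
    tirf:
      field_size_px: [96, 96]
      n_frames: 150
      diffusion_um2_s: 3.0e-3
      dwell_mean_s: 1.5
      birth_rate_per_frame: 1.0
tracking:
  min_length: 5
  max_disp_px: 2.5
  max_gap_frames: 2
dynamics:
  n_lags: 4
dwell:
  threshold_frac: 0.5
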