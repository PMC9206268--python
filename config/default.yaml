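# Annotated default configuration. Every key is optional; omitted keys use
# the library defaults shown here.

io:
  # CSV layout of per-trial exports: column names (or 0-based indices) and
  # the source position unit ("mm" for plate exports, "m" for tracker logs).
  time_col: time_s
  ml_col: ml
  ap_col: ap
  unit: mm
  # Declared sampling rate; trials whose inferred rate differs by more than
  # fs_tolerance (relative) are rejected, never resampled.
  expected_fs: 100.0
  fs_tolerance: 0.01

preprocess:
  # Zero-phase Butterworth low-pass. "order" is the effective magnitude
  # order of the composed forward-backward filter; the default design runs
  # a 2nd-order pass each way (4th-order roll-off, zero phase).
  order: 4
  cutoff_hz: 5.0
  design: one_pass_each_way_2nd   # or one_pass_each_way_4th
  # Sway origin: per-trial mean ("trial_mean") or the recorded coordinate
  # origin ("file_origin").
  origin: trial_mean

simulate:
  # Cohort shape: subjects per age group, trial length and rate.
  n_per_group: 27
  fs: 100.0
  duration_s: 120.0
  # Shared slow (center-of-mass) component: bandwidth and per-axis base
  # amplitude (mm). Condition multipliers scale it with task difficulty;
  # ML grows more than AP when the stance narrows.
  latent_cutoff_hz: 0.3
  base_amp_mm: {ml: 2.5, ap: 3.5}
  condition_mults:
    ml: {W-EO: 1.0, W-EC: 1.25, N-EO: 1.9, N-EC: 2.5}
    ap: {W-EO: 1.0, W-EC: 1.3, N-EO: 1.45, N-EC: 1.8}
  # High-frequency regulatory component: band (Hz), LD amplitude (mm), and
  # how much larger it registers at the force plate than at the lumbar level.
  hf_band_hz: [0.5, 5.0]
  ld_hf_amp_mm: {ml: 0.12, ap: 0.12}
  cop_hf_gain: 3.0
  # Older-group effects: slow-amplitude multiplier and per-axis
  # high-frequency activity multipliers (ML > AP).
  group_amp_mult: 1.35
  group_hf_mult: {ml: 2.2, ap: 1.5}
  # Fraction of LD slow variance shared with CoP, and per-subject lognormal
  # spreads of the shared frailty and per-system activity factors.
  lf_share: 0.9
  subject_amp_sigma: 0.35
  subject_act_sigma: 0.30
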