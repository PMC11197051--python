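# All label-noise terms zero: ground truth == virtual == mirror exactly.
# EMG is still synthesized (amplitude-modulated noise is signal, not label noise).
coupling: 0.0
drift_step_sd: 0.0
drift_max: 0.25
mimic_lag_mean_s: 0.0
mimic_lag_sd_s: 0.0
mirror_jitter_sd_s: 0.0
mimic_mag_err_mean: 0.0
mimic_mag_err_sd: 0.0
mirror_mag_err_sd: 0.0
emg_baseline: 0.05
synergy:
  electrodes_per_dof: 6
  gain_range: [0.5, 1.5]
  seed: 20240522
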