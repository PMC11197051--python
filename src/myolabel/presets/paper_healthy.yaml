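# Healthy-cohort preset, calibrated with scripts/calibrate_preset.py so the
# label-quality metrics recover the reported cohort values on simulated
# 18-movement / 10-rep sessions:
#   biomechanical coupling ~ 11.43 %   (sets `coupling`, calibrated first)
#   resting-position drift ~ 7.07 %    (sets `drift_step_sd`, second)
#   mimic magnitude error  ~ 12.89 +/- 1.45 %  (mimic_mag_err_mean / _sd)
#   timing: positive-only mimic reaction lag, larger two-sided mirror jitter
#   (orderings of the timing/magnitude metrics; see docs/methods.md).
coupling: 0.2569
drift_step_sd: 0.00946
drift_max: 0.25
mimic_lag_mean_s: 0.140
mimic_lag_sd_s: 0.015
mirror_jitter_sd_s: 0.025
mimic_mag_err_mean: -0.1289
mimic_mag_err_sd: 0.0145
mirror_mag_err_sd: 0.010
emg_baseline: 0.05
synergy:
  electrodes_per_dof: 6
  gain_range: [0.5, 1.5]
  seed: 20240522
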