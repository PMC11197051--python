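# myolabel

Tools for studying how training data should be collected for regression-based
myoelectric prosthesis control. Supervised decoders that map surface EMG
(sEMG) to continuous hand kinematics need labeled training data, but after
hand amputation the intended kinematics cannot be measured directly. Two
labeling paradigms dominate practice:

* **mimic training** — the user copies preprogrammed movements of a virtual
  hand/prosthesis, and the preprogrammed kinematics serve as the labels;
* **mirror training** — the user performs bilaterally mirrored movements and
  motion capture of the intact contralateral hand provides the labels.

`myolabel` simulates bilateral training sessions with a known ground-truth
hand, quantifies how accurately each paradigm's labels represent that ground
truth, and measures how label quality propagates into offline decoder
performance as a function of training-set size. It is aimed at researchers
in myoelectric control and neural engineering who want a controlled,
fully-seeded testbed for training-data questions.

## What is inside

* **Synthetic session generator** (`simulate`): preprogrammed trapezoidal
  movements over 8 hand/wrist degrees of freedom (0.7 s ramp, 0.1 s hold,
  0.7 s return, 1 s inter-trial rest; 18- and 14-movement protocols), a
  ground-truth hand with positive reaction lag, per-trial magnitude error,
  biomechanical coupling and resting-posture drift, a mirror hand with
  two-sided timing jitter, and surrogate 32-channel 1 kHz EMG whose envelope
  is a synergy map of the rectified joint angles.
* **Feature extraction** (`features`): 300-ms mean-absolute-value (MAV)
  features at 30 Hz for 32 single-ended channels and all 496 differential
  pairs (528 channels), joint-angle normalization to [-1, 1], and
  cross-correlation lag alignment.
* **Label-quality metrics** (`metrics`): biomechanical coupling, resting
  drift, spatial and temporal accuracy/precision of per-trial peaks, and
  trace RMSE, in percent of full deviation and milliseconds.
* **Decoders** (`kalman`, `nnet`): a position-state Kalman filter trained by
  least squares/ridge regression with correlation-based channel selection,
  the threshold/rescale runtime rule of the modified Kalman filter, and a
  windowed feed-forward network over a `history x channels` spatiotemporal
  EMG image with trial-held-out early stopping.
* **Evaluation and statistics** (`evaluation`, `stats`): shuffled k-fold,
  movement-stratified, session-balanced train/test splits; dataset-size
  sweeps (10-55 trials) with paired folds across paradigms; one-sample and
  paired t-tests, three-way ANOVA, Holm-adjusted post-hoc tests.
* **I/O and CLI** (`io`, `cli`): lossless HDF5 session archives, YAML run
  configs with manifests, and `myolabel simulate|features|metrics|train|
  evaluate|report` subcommands.

## Worked example

```python
from myolabel import (build_schedule, make_params, simulate_participant,
                      label_quality_report)

schedule = build_schedule("biomech", reps=10)            # 18 movements x 10
params = make_params("paper_healthy", seed=42)           # calibrated preset
session = simulate_participant(schedule, params)

for paradigm in ("mimic", "mirror"):
    r = label_quality_report(session, paradigm)
    print(f"{paradigm:6s}  mag {r.mag_err_mean_pct:5.2f} +/- {r.mag_err_disp_pct:4.2f} %   "
          f"timing {r.timing_err_mean_ms:6.1f} +/- {r.timing_err_disp_ms:4.1f} ms   "
          f"rmse {r.rmse:.3f}")
r = label_quality_report(session, "mimic")
print(f"coupling {r.coupling_pct:.2f} %   drift {r.drift_pct:.2f} %   "
      f"estimated reaction lag {r.lag_s*1000:.0f} ms")
```

```
mimic   mag 13.62 +/- 8.47 %   timing  -16.3 +/- 26.8 ms   rmse 0.164
mirror  mag  0.63 +/- 0.52 %   timing   -2.2 +/- 28.8 ms   rmse 0.013
coupling 11.29 %   drift 7.18 %   estimated reaction lag 133 ms
```

Reading the output: this simulated participant's hand leaks about 11% of
full deviation into non-target joints during individuated movements and
drifts about 7% from its initial rest posture — deviations the mimic labels
(the ideal virtual-hand trace) cannot represent. The mirror labels track the
ground-truth hand far more closely in magnitude (0.6% vs 13.6% peak error)
and in overall RMSE, while their peak-timing errors are *less* consistent
(28.8 vs 26.8 ms dispersion): reaction lag relative to the virtual hand is
fairly stereotyped (and largely removed by the cross-correlation
alignment, here 133 ms), whereas bilateral synchrony jitters in both
directions.

The same pipeline scales to cohorts and decoder sweeps:

```sh
myolabel simulate --protocol ml --reps 20 --seed 1 --out session.h5
myolabel metrics --session session.h5 --out report.tsv
myolabel evaluate --config config.yaml   # cohort + size sweep + statistics
```

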