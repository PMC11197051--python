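# Methods

## The question being modeled

Regression decoders for myoelectric prostheses are trained on pairs of EMG
features and *intended* kinematics. The intended kinematics are not
observable after amputation, so practice substitutes either the
preprogrammed motion the user copies (mimic training) or motion capture of
the contralateral hand during bilateral movements (mirror training).
`myolabel` builds a generative model of a bilateral training session in
which the ground-truth hand *is* observable, so label error of each
paradigm can be measured exactly and pushed through the decoding pipeline.

## Session generator

A session is a sequence of trials on an 8-DOF normalized joint space
(D1–D5 flexion/extension, D1 abduction/adduction, wrist flexion/extension,
wrist pronation/supination; +1 = full flexion/pronation, −1 = full
extension/supination, 0 = rest). Each trial is a 1 s inter-trial rest
followed by a trapezoidal excursion of the target DOF(s): 0.7 s linear ramp
to ±1, 0.1 s hold, 0.7 s return (45 samples at 30 Hz). The `biomech`
protocol enumerates 18 movements (individuated flexion and extension of
each digit, wrist flexion/extension, wrist pronation/supination, D1
abduction/adduction, power grasp, hand open); the `ml` protocol enumerates
the 14 movements of a multi-articulate prosthetic arm's DOF set (D1–D3
flexion/extension, the wrist pairs, D1 ab/adduction, and grip close/open —
the grip is one DOF of the arm even though it maps to simultaneous D1–D5
motion in joint space). Every movement is repeated consecutively before the
next begins, and a trailing rest closes the session.

The **ground-truth hand** reproduces each preprogrammed trial with four
imperfections, applied in this order and clipped to [−1, 1] last so the
normalized-range invariant survives downstream:

1. *Magnitude error*: the trial profile is scaled by `1 + ε`,
   `ε ~ N(mimic_mag_err_mean, mimic_mag_err_sd)` per trial.
2. *Reaction lag*: the profile is delayed by `L ~ N(mimic_lag_mean_s,
   mimic_lag_sd_s)` truncated at zero — the hand always lags the prompt.
   Lags are fractional-sample shifts on the 30 Hz grid via linear
   interpolation (the grid on which all timing metrics are computed).
3. *Biomechanical coupling*: each target DOF's scaled profile leaks into
   every non-target DOF with fraction `coupling_matrix[j, k]` (zero
   diagonal, uniform off-diagonal by default; leakage never feeds back into
   other target DOFs).
4. *Resting drift*: a per-DOF random walk over rest intervals — one
   `N(0, drift_step_sd)` increment per interval, clipped to ±`drift_max` —
   added to the whole trial segment that follows. A random walk is the
   simplest persistent-offset process with a single spread parameter.

The **mirror hand** replays the same latent trial (same ε, L, coupling,
drift) with an extra two-sided jitter `J ~ N(0, mirror_jitter_sd_s)` and
magnitude noise `η ~ N(0, mirror_mag_err_sd)`: it tracks the ground-truth
hand, not the prompt. The mimic hand's lag is strictly positive while the
mirror offset `L + J − L = J` is zero-mean — the asymmetry that drives the
timing-precision results.

**Surrogate EMG** is amplitude-modulated Gaussian noise: per-channel
envelope `e(t) = baseline + G⁺·max(θ, 0) + G⁻·max(−θ, 0)` with nonnegative
32×8 synergy matrices (each DOF direction recruits a sparse random electrode
subset), linearly upsampled to 1 kHz and multiplied by independent standard
normals. The closed form makes the feature stage testable: the expected
300-ms MAV of the raw signal is `e(t)·sqrt(2/π)` (mean of a half-normal).
This is deliberately not a physiological model — no motor-unit pools,
conduction velocity, fatigue or electrode-shift nonstationarity — because
only the MAV envelope reaches the decoders.

All draws come from one generator seeded by `ParticipantParams.seed` in a
fixed order (magnitude errors, lags, mirror magnitude noise, mirror jitter,
drift increments, EMG noise), so identical inputs give bit-identical
sessions.

### The `paper_healthy` preset

`scripts/calibrate_preset.py` fixes the preset in a stated order: the
coupling fraction first (the coupling metric is linear in it), then the
drift step SD (secant iteration on the cohort drift mean), with
magnitude/timing noise set directly from the cohort values they represent.
Current values: coupling 0.2569, drift step SD 0.00946/interval (max
±0.25), reaction lag 140 ± 15 ms, mirror jitter SD 25 ms, magnitude error
−12.89 ± 1.45 %, mirror magnitude noise SD 1 %. On simulated 7-participant
cohorts (18 movements × 10 reps) the metrics read back ≈ 11.4 % coupling
and ≈ 7.1 % drift. `sample_cohort` adds per-participant lognormal scale
factors (CV 8–13 %) on the coupling/drift/lag/magnitude knobs so cohort
dispersion is realistic rather than degenerate. The `noise_free` preset
zeroes every label-noise term; in that limit ground truth, virtual and
mirror traces are identical sample-for-sample, which anchors the metric
suite at exactly zero.

## Features and alignment

MAV features use a trailing (causal) rectangular window — 300 ms, emitted
at the kinematic timestamps (30 Hz) so no label resampling is needed.
Partial windows at the stream start average over the available samples
rather than padding. Differential channels are computed on raw differences
`x_i − x_j` (i < j, lexicographic order after the 32 single-ended
channels), then rectified and averaged; a differenced pair of identical
channels is exactly zero. Window anchors are placed at
`round(k · raw_rate / out_rate)`, which supports the 1 kHz → 30 Hz ratio
without requiring an integer decimation factor.

Joint-angle normalization maps the per-participant rest baseline (mean over
a leading rest window, default 15 s) to 0 and the flexion/extension
extremes to ±1 piecewise-linearly; extremes default to the per-session
observed min/max when no calibration trial is supplied.

Reaction-lag alignment cross-correlates the summed absolute label deviation
against the summed mean-centered features over integer shifts within
±0.5 s, breaking ties toward the smallest then the negative lag. Inside the
label-quality report (and dataset building) the reference is a *zero-phase*
(centered) MAV envelope: a causal window carries a ~150 ms group delay that
would otherwise be folded into the estimated reaction lag and overcorrect
the labels by half a window. Aligned mimic labels are shifted on the
kinematic clock; exposed edge samples are zero-filled, which is exact
because sessions begin and end at rest.

## Label-quality metrics

* **Coupling**: per trial, the mean absolute non-target-DOF deviation over
  the movement segment, referenced to the trial's own preceding rest tail
  (0.5 s) so the drift offset cancels and the two phenomena are not
  double-counted; mean across DOFs, median across trials.
* **Drift**: mean absolute deviation from the session-initial rest posture
  over each later rest interval, all DOFs; median across intervals.
* **Spatial accuracy/precision**: mean and dispersion across trials of
  `|peak(labels) − peak(truth)|` on the target DOFs (combination trials
  average the per-DOF peaks), in percent. The dispersion estimator defaults
  to a standard deviation (the unit-consistent reading of the reported
  precision values) with a `variance` switch.
* **Temporal accuracy/precision**: mean and dispersion of the signed
  per-trial peak-time difference. Peaks are `argmax |value|` with ties
  broken to the earliest sample, so on trapezoid plateaus timing errors are
  quantized to the 33.3 ms sample grid; sub-sample means should not be
  over-interpreted, but orderings between paradigms are stable. Peak-search
  windows extend through the following rest so a lagged plateau is never
  cut off.
* **RMSE**: pooled over all DOFs and samples, normalized units.

Mimic labels are lag-corrected before metric computation; mirror labels are
used as recorded. Coupling and drift are properties of the ground-truth
hand and are identical under either paradigm.

## Decoders

The Kalman filter state is the 8 joint positions (no velocity
augmentation, keeping the state model directly interpretable). `A` and `W`
come from least squares of `x_t` on `x_{t−1}` over within-trial pairs; the
normal equations are ridge-loaded because preprogrammed labels can make
DOFs that only move together exactly collinear. Observations are the 48
feature columns (default) with the highest absolute correlation to any
DOF; `H` is a ridge regression of those features on the kinematics and `Q`
its residual covariance diagonally loaded by the same `ridge_lambda`
(default 1e-3). Filtering starts from a zero state with a diffuse prior
(variance 1e2) and clips outputs to [−1, 1]. The runtime modification
(MKF) zeroes magnitudes below a 20 % threshold and linearly rescales the
remainder to full range, applied on the magnitude with the sign restored —
odd, continuous at the threshold, and monotone; it is an online-control
post-process and is not applied in the offline evaluation.

The nonlinear decoder is a feed-forward network over the flattened
`history × channels` spatiotemporal image of the most recent feature
samples (default history 10, seven hidden layers + output = eight weighted
layers, Adam at 1e-4). Windows are zero-padded at trial starts so
predictions are causal and never mix trials. Validation reserves whole
trials (default 5) from the training split; early stopping restores the
best validation weights (patience 20 of 200 epochs). A `small_spec`
(history 5, two hidden layers, 1e-3, 40 epochs) is the desk-scale default
for reduced-channel analyses; the full spec is the same code path.

## Evaluation

Folds are built at trial granularity (never splitting a trial between
train and test, avoiding temporal leakage) and stratified by movement:
each fold reserves `n_train` trials per movement, drawn equally (to within
one trial, remainder rotated across folds) from each recording session,
and tests on the rest. Folds are constructed once per (size, seed) and
reused across paradigms and algorithms so comparisons are paired. Fold
error is computed against the held-out labels of the same paradigm: an
oracle emitting the test labels scores exactly zero. The per-condition
summary follows the per-DOF absolute error per time point → median over
time per DOF → median across the 8 DOFs → median across folds chain, with
an `aggregate="rmse"` switch for conventional per-DOF RMSE. Cohort
statistics use scipy t-tests and a statsmodels type-II ANOVA (paradigm ×
algorithm × size, single-level factors dropped); post-hoc pairwise tests
are reported uncorrected with a Holm-adjusted column alongside.

Desk-scale defaults used by the shipped analyses: 7-participant cohorts at
18 movements × 10 reps for the metric suite; one participant × three
14-movement × 20-rep sessions, 11 electrodes (66 feature channels), the
small network spec and 3 folds for the learning-curve sweep. These sizes
are the package's reference configuration; the 528-channel, 10-fold,
full-network path is available through `RunConfig`.

## What the generator does and does not show

Passing the test suite demonstrates that the metric definitions recover
injected generator parameters (coupling, drift SD, lag mean, jitter SD,
magnitude SD, each within ~10 % on 50-trial single-knob sessions), that the
calibrated cohort reproduces the target coupling/drift levels and the full
mirror-vs-mimic sign pattern (magnitude accuracy and precision, timing
accuracy and RMSE favor mirror; timing precision favors mimic), and that
decoder test error falls with training-set size for both paradigms.

Two limits deserve emphasis. First, timing metrics live on the 30 Hz grid;
their absolute means are quantization-dominated even though orderings are
robust. Second, the EMG surrogate is stationary and low-noise by
construction: its features carry far more information per trial than real
sEMG, so decoders approach their error floors within tens of trials, and
each paradigm's floor is set by its own unpredictable label noise. Because
the calibrated mirror jitter exceeds the post-alignment mimic lag
dispersion (as the timing-precision metrics themselves show), the windowed
network's floor under mirror labels sits slightly *above* its floor under
mimic labels on this synthetic data. With real EMG — heterogeneous,
nonstationary, high-dimensional — decoders remain estimation-limited at
these dataset sizes, a regime in which the mirror paradigm's more faithful,
EMG-consistent labels pay off; reproducing that regime would require EMG
nonstationarity modeling that is outside this generator's scope. Findings
on this testbed therefore transfer to real recordings only where they
concern label geometry and the data-efficiency of the pipeline, not
absolute decoder error or paradigm rankings at the error floor.
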