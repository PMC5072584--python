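# Methods

`wristspeed` estimates average walking speed from a wrist-worn 9-axis IMU
(accelerometer, gyroscope, magnetometer at 100 Hz) by regressing per-epoch
signal features onto speed. This note records the models, the defaults and
why, the numerical choices, and what the synthetic cohort does and does not
emulate.

## Signal pipeline

1. **Low-pass filtering.** All nine channels are filtered with a 4th-order
   Butterworth low-pass at 20 Hz, applied forward–backward
   (`scipy.signal.sosfiltfilt`) so the filter is zero-phase and epoch
   boundaries stay aligned with the ground-truth timeline. The order is a
   package choice; daily-living movement lies well below the cutoff.

2. **Orientation.** An error-state quaternion Kalman filter estimates the
   sensor-to-navigation rotation `R_s→n`. Conventions: navigation frame
   z-up, x = magnetic north, y = west; quaternions scalar-first; the
   accelerometer measures specific force, so a static sensor reads
   `R^T (0, 0, +9.81)`.
   - State: 3 attitude-error + 3 gyro-bias components. Gyro propagation
     uses the midpoint (trapezoidal) angular rate between consecutive
     samples — first-order integration leaves a visible error floor at
     100 Hz with swing rates of 2–3 rad/s.
   - Accelerometer update: gravity-direction measurement, gated to samples
     with `||a| − g| < 0.5 m/s²`. The gate alone is insufficient: external
     acceleration perpendicular to gravity can be large while the norm is
     close to `g`, and treating such samples as gravity observations drags
     the attitude by several degrees during walking. The measurement
     variance is therefore inflated by `1 + (|ω|/ω_ref)²` with
     `ω_ref = 0.01 rad/s`: the update keeps its authority at standstill
     (where it is valid) and is distrusted while the arm swings.
   - Magnetometer update: corrects heading only (the innovation is the
     horizontal-plane angle of the rotated field against north), so
     magnetic disturbance cannot tilt the attitude.
   - Initialization: TRIAD on the first 0.5 s (mean accelerometer = up,
     horizontal mean magnetometer = north), accepted only if the mean
     accelerometer norm is within 20 % of `g`; the gyro bias is
     initialized from the static window mean. If no static window exists
     the same TRIAD runs on the moving means with inflated covariance.
   - Tunings (unitless, configurable): `q_gyro 1e-4`, `q_bias 1e-8`,
     `r_acc 0.1`, `r_mag 0.1`.

3. **Variables.** Three scalar streams per trial:
   - `acc` — per-sample norm of the raw specific force;
   - `ext_acc` — norm of `R_s→n a_s − (0,0,9.81)`;
   - `pca_acc` — per 5-s epoch, the horizontal (x, y) components of the
     external acceleration are mean-centered, the first principal axis of
     their 2×2 covariance is found, and the centered series is projected
     onto it. The projection is invariant to heading up to one global
     sign per window; the sign is fixed by requiring non-negative
     skewness (ties: first nonzero sample positive) so results are
     reproducible. PCA support is one feature epoch: the paper-scale
     direction changes happen between epochs, and a per-epoch axis keeps
     the projection stationary within the unit of feature extraction
     (per-trial support is available via the window list).
     Mean-centering discards the epoch-mean horizontal acceleration,
     which is ≈ 0 for steady walking. A degenerate window (no horizontal
     motion) yields zeros and a warning rather than an error.

4. **Features.** Streams are cut into non-overlapping 5-s epochs
   (500 samples). Per epoch: 8 time-domain statistics — mean, sample SD,
   median, mode, mean absolute value, mean-crossing count, signal
   magnitude area `Σ|x|`, energy `Σx²` — and 40 frequency-domain
   features: the single-sided amplitude spectrum `2|X_k|/N` of a 512-point
   zero-padded FFT, bins 1–40 (≤ 7.8125 Hz). The "mode" of a continuous
   signal is defined as the center of the most populated of 50 equal-width
   bins over the epoch range (ties → lowest bin). Mean crossings count
   sign changes of `x − mean(x)` with zeros treated as positive. DC is
   excluded from the FD set because it duplicates the TD mean
   (`fd_include_dc` flag provided). No FFT window function is applied;
   leakage is consistent across epochs and absorbed by the regressor.
   Generalized models append subject height (m) and weight (kg).

## Regressors

**GPR.** `y = f(x) + ε`, `ε ~ N(0, σ_n²)`, with the squared-exponential
ARD kernel `k(x,x′) = σ_f² exp(−½ Σ_d (x_d−x′_d)²/l_d²)`. Posterior mean
and variance use the standard expressions with `K + σ_n² I`; the noise
term follows from the observation model, and a jitter of `1e-10·σ_f²`
(escalated ×10 up to `1e-6` on Cholesky failure) guards the
factorization. Features and targets are z-scored internally (prior mean 0
on standardized targets); the standardization record is stored with the
model. Hyperparameters maximize the log marginal likelihood by L-BFGS-B
in log space with analytic gradients, bounds `log l ∈ [−5, 5]`, seeded
random restarts.

*Noise floor.* On pooled multi-subject data the marginal likelihood
drives `σ_n → 0`: the 50-dimensional ARD kernel can memorize each
training subject's signature, which triples leave-subject-out error. The
optimizer therefore lower-bounds `σ_n` (0.15 standardized-target units
by default in protocol runs) — an explicit statement that
between-subject residual variation is noise with respect to a
generalized model. The floor is a parameter (`noise_floor`) and can be
released for single-subject fits. Length scales are initialized at `√D`
(the median-distance heuristic): initializing at 1 in a 50-dimensional
standardized space makes the starting kernel effectively diagonal and
strands the optimizer in a memorization basin.

*Mean function.* The plain zero-mean posterior (the equations above) is
the `GprModel` default and what the oracle tests verify. A zero-mean GP,
however, reverts to the cohort-mean speed for queries outside the
training distribution — for a generalized model this means a subject
whose gait style sits at the edge of the cohort gets pulled toward the
average, and the GP can lose to a plain linear fit exactly where
generalization is hardest. Protocol runs therefore use the standard
semi-parametric (explicit-basis-function) construction,
`mean_function="lasso"`: a sparse linear trend is fitted first (ℓ1
penalty chosen by the same 10-fold CV as the standalone Lasso) and the
zero-mean SE-ARD GP models its residuals. Out of distribution the GP
correction vanishes and predictions fall back to the linear trend;
within the training distribution the correction captures what the linear
model cannot (it measurably helps on most synthetic cohorts and slightly
hurts on some — the comparison with the standalone Lasso is a genuine
test of the nonparametric component). A ridge-based trend
(`mean_function="linear"`, GCV-penalized) is also available. Note that
the marginal likelihood decides how much the correction contributes: on
large, well-fitted cohorts it can shrink the GP signal variance to its
bound, in which case the semi-parametric GPR's predictions coincide with
its sparse linear trend (and with the standalone Lasso).

**Lasso.** `½ Σ (y_i − β₀ − x_iᵀβ)² + λ Σ|β_j|`, intercept unpenalized,
solved by cyclic coordinate descent with exact soft-thresholding (true
zeros). Features are standardized; coefficients are reported in original
units. Convergence: largest coefficient change per sweep < 1e-8 (relative
to coefficient scale), cap 10 000 sweeps. `λ` is selected by 10-fold
cross-validation over 50 log-spaced values from `λ_max` down to
`1e-4 λ_max`, folds drawn once per seed. On the small-`λ` end the FFT-bin
columns are nearly collinear and coordinate descent zigzags without
improving the fit; the CV path therefore runs best-effort fits (tolerance
1e-5, objective-plateau stop 1e-10 relative, 2000-sweep cap) while the
final fit at the selected `λ` is strict.

## Evaluation protocol

For each subject *n*, 20 % of their epochs are sampled as test data.
**Generalized**: the model is trained on all epochs of the other subjects
(so it is fitted once per subject and evaluated on each of the 10
resampled test sets — identical to refitting, since the training set does
not depend on the repeat). **Subject-specific**: trained on the remaining
80 % of subject *n*'s epochs, refitted per repeat. Errors are averaged
over repeats, then over subjects. All randomness derives from one master
seed through `SeedSequence(master, spawn_key=(subject_index, repeat))`.

Metrics: MAE% is the mean of `|ŷ−y|/y × 100` (the only reading that
yields percent units next to an RMSE in cm/s); RMSE is in cm/s. Two
precision figures are reported and labeled: the SD of the per-epoch error
quantities (pooled) and the SD of per-subject means. Speed regimes are
slow [50, 100), normal [100, 150), fast [150, 200] cm/s, bucketed by true
speed. Bland–Altman: bias = mean(ŷ−y), limits = bias ± 1.96·sample SD.
Method comparisons use one-way ANOVA on per-subject mean MAE% (per-epoch
errors would pseudo-replicate within subjects). Pearson r and the
least-squares line of ŷ on y accompany pooled predictions. A slow-regime
specialization is available by filtering training epochs to < 100 cm/s.

## Synthetic cohort

The simulator produces labeled 9-axis wrist recordings from a planar
pendulum-arm model composed with a heading profile and a fixed
sensor-mount rotation. Orientation, body rate and specific force are
evaluated in closed form, so the simulator is also the oracle for the
orientation filter and the gravity-compensation step.

Kinematics, with `v` the walking speed (m/s):

- swing angle `θ = A(v)·E(t)·[sin φ + h·sin(2φ + δ)]`,
  `A(v) = swing_gain·v` (default 0.3 rad/(m/s)); the second harmonic
  (`h ≈ 0.25`, per-subject phase) reflects asymmetric, non-sinusoidal
  pendular swing;
- stride frequency `f(v) = base_step_freq + freq_gain·v`
  (defaults 0.6 Hz, 0.4 Hz/(m/s)) places the dominant peaks in the
  0.8–1.6 Hz band; the phase `φ` carries a slow sinusoidal frequency
  modulation of CV 3 % (stride-time variability);
- `E(t)` is a 1-s raised-cosine onset ramp per segment (a discontinuous
  swing start would put a step into the gyro);
- the shoulder translates at `v` along the heading and oscillates at the
  step frequency `2f`: fore-aft and vertical components with displacement
  gains 0.02 and 0.03 m per radian of swing amplitude, per-subject phase;
- heel-strike transients: band-limited (2.5–12 Hz) seeded noise,
  vertical-dominated (0.35/0.35/1 axis weights riding with the heading),
  RMS scaling like the gait oscillation (gain 0.02). This broadband
  content is what the norm variables fold into their spectra via
  rectification while the horizontal principal-axis projection largely
  rejects it;
- sensors: accelerometer `R^T(a_ext + g) + noise`, gyroscope
  true rate + constant bias + noise, magnetometer `R^T m_n + noise` with
  `m_n` = unit horizontal north + 0.5 vertical; gravity 9.81 m/s².
  Default noise: acc 0.05 m/s², gyro 0.005 rad/s, bias ~ N(0, 0.01 rad/s)
  per trial, mag 0.02 — MEMS-grade, all overridable, fully seeded.

Each trial starts with a 2-s standstill lead-in (filter initialization;
heading wander starts at the walk onset because a standing subject does
not yaw-drift). Ground truth per 5-s epoch is the mean of the speed
profile, anchored at the end of the lead-in.

Cohort sampling (all seeded): height 1.69 ± 0.08 m, weight 65 ± 10 kg;
arm length 0.41·height ± 0.01 m; stride frequency follows pendulum
scaling with the sampled arm length ± 0.015 Hz; `freq_gain` 0.4 ± 0.015
(the timing couplings are calibrated so that leave-subject-out accuracy
lands in the range the method demonstrably attains across subjects —
wider spreads make every variable and model collapse to the same
between-subject error floor);
`swing_gain` 0.3 ± 0.05 (amplitude style is the component of wrist
kinematics anthropometry does not explain — this is why time-domain
amplitude features generalize poorly across subjects while spectral
features transfer); oscillation/impact transmission gains ± 30 %; mount
misalignment up to 15°. Trials: 4 per regime per subject, steady speeds
drawn uniformly within slow/normal/fast, constant base heading plus a
0.1-rad sinusoidal wander.

**What the generator does not emulate** (so what passing tests do not
show about real data): 3-DOF shoulder kinematics, posture changes and
non-walking activity, arm-constrained walking (pockets, bags),
magnetometer hard/soft-iron disturbance, sensor-specific (Xsens) error
models, GPS, and any real inter-subject correlation structure beyond the
anthropometric couplings listed above. Absolute error levels on the
synthetic cohort are therefore not predictions of human-subject accuracy;
the cohort is built to reproduce the qualitative structure the method
relies on (speed–frequency/amplitude coupling, heading independence,
harmonic-rich swing versus folded, impact-contaminated norms).

## Problem sizes

The main evaluation cohort is 15 subjects × 12 trials × 20-s steady-speed
walks (the indoor 30-m protocol lasts 15–50 s depending on regime; a
fixed 20 s balances epochs across regimes), giving 4 epochs per trial and
a leave-subject-out training size of 672. Seed-robustness checks (variable
and model orderings) use 15 subjects × 3 trials × 25 s over five master
seeds — keeping the study's cohort size, which stabilizes the
across-subject mean against single-outlier domination, with one trial
per regime. GPR protocol fits use 1 restart and 150 L-BFGS iterations.

## Known limitations

- The orientation filter's accelerometer gating is heuristic; sustained
  smooth accelerations that keep `|a| ≈ g` (turntable-like motion) would
  be absorbed as tilt.
- Per-epoch PCA re-estimates the axis every 5 s; pathological epochs with
  isotropic horizontal motion fall back to a zero projection.
- The GPR noise floor trades single-subject sharpness for generalization;
  subject-specific models may prefer a smaller floor.
- The λ grid's small end is effectively unregularized least squares on
  collinear features; the CV path handles it best-effort (see above).
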