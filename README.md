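# wristspeed

Walking speed is a vital sign: it tracks cognitive decline, fall risk,
neurological disease and general frailty. Measuring it continuously in
daily life requires a sensor people will actually wear — a wrist-worn
IMU (watch or band) rather than a foot- or waist-mounted unit.
`wristspeed` implements a regression pipeline that estimates average
walking speed from the arm-swing motion recorded by a wrist-worn 9-axis
IMU (tri-axial accelerometer, gyroscope and magnetometer at 100 Hz), for
researchers in digital health and biomechanics.

## Method

The wrist signal is reduced to one of three scalar variables of
increasing sophistication:

- **acc** — the raw specific-force norm `|ˢa|`;
- **ext-acc** — the external (gravity-compensated) acceleration norm:
  sensor fusion (an error-state quaternion Kalman filter over
  accelerometer/gyro/magnetometer) yields the rotation `R_s→n` into a
  local-level frame, then `ⁿa_ext = R_s→n ˢa − ⁿg` and
  `ext-acc = |ⁿa_ext|`;
- **pca-acc** — the horizontal components of `ⁿa_ext` projected, per 5-s
  epoch, onto their first principal axis. The principal axis is the arm
  swing direction, so the projection follows the swing while remaining
  invariant to walking direction (up to a deterministic sign).

Each variable stream is low-pass filtered (4th-order zero-phase
Butterworth, 20 Hz), cut into 5-s epochs, and summarized by 8 time-domain
statistics and the first 40 single-sided FFT amplitude coefficients
(512-point FFT, < 8 Hz). Walking speed is regressed on these features with

- **Gaussian-process regression** using a squared-exponential ARD kernel
  `Σ(xᵢ,xⱼ) = σ_f² exp(−½ (xᵢ−xⱼ) W⁻¹ (xᵢ−xⱼ)ᵀ)`, hyperparameters by
  marginal-likelihood maximization, predictive mean/variance in closed
  form; and
- **Lasso** (ℓ₁-penalized least squares) by coordinate descent, with the
  penalty chosen by 10-fold cross-validation,

under two protocols: *generalized* (leave-subject-out: the model for a
subject is trained on everyone else) and *subject-specific* (trained on
the same subject's held-in 80 %), each with 20 % test samples resampled
10 times. Accuracy is reported as MAE (%) and RMSE (cm/s) with SDs,
per speed regime (slow 50–100, normal 100–150, fast 150–200 cm/s),
plus Bland–Altman agreement, Pearson correlation and ANOVA comparisons.

Because no public wrist-IMU walking dataset accompanies the method, the
package includes a synthetic cohort generator (`wristspeed.synthetic`): a
pendulum-arm model whose swing frequency and amplitude grow with speed,
composed with gait oscillation, heel-strike transients, heading changes,
gravity in the rotating sensor frame, and MEMS-grade sensor errors — with
analytic ground-truth orientation and external acceleration, so the whole
pipeline is testable end to end. See `docs/methods.md` for the model and
its limits.

## Worked example

```python
import numpy as np
from wristspeed import (
    SubjectProfile, TrialPlan, NoiseSpec, simulate_trial,
    estimate_orientation, compute_ext_acc,
)

profile = SubjectProfile()                      # 1.69 m, 65 kg, 0.7 m arm
plan = TrialPlan(segments=[(20.0, 120.0)],      # 20 s at 120 cm/s
                 heading=0.3, noise=NoiseSpec.zero())
rec, truth = simulate_trial(profile, plan)

orient = estimate_orientation(rec)              # quaternion Kalman filter
nav, ext = compute_ext_acc(rec, orient)

err = np.degrees(2 * np.arccos(np.clip(np.abs(
    np.sum(orient.quaternions * truth.quaternions, axis=1)), -1, 1)))
print(f"attitude RMS error: {np.sqrt(np.mean(err**2)):.3f} deg")
rms = np.sqrt(np.mean((ext.values - np.linalg.norm(truth.a_ext_n, axis=1))**2))
print(f"ext-acc RMS error:  {rms:.4f} m/s^2")
print(f"epoch speeds:       {truth.epoch_speeds} cm/s")
```

Output:

```
attitude RMS error: 0.099 deg
ext-acc RMS error:  0.0140 m/s^2
epoch speeds:       [120. 120. 120. 120.] cm/s
```

On zero-noise data the fusion filter tracks the simulated wrist to a
tenth of a degree and the gravity-compensated acceleration matches the
analytic ground truth to ~0.01 m/s²; the per-epoch labels are the mean of
the commanded speed profile.

A full experiment from the shell:

```bash
wristspeed run --variable pca-acc --model gpr --features td_fd \
               --mode generalized --seed 0 --out results/
wristspeed simulate --subjects 15 --seed 0 --out data/   # export a cohort
```

`run` simulates a cohort, extracts features, fits the chosen model under
the chosen protocol and writes `accuracy.csv`, `regimes.csv`,
`bland_altman.csv` and `report.json`.

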