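"""Synthetic wrist-IMU walking trials with analytic ground truth.

The simulator implements the simplest kinematic model that reproduces the
couplings a wrist-worn speed estimator exploits: arm swing whose frequency
and amplitude both grow with walking speed, forward/vertical gait
oscillation, gravity expressed in a rotating sensor frame, heading
changes, and MEMS-grade sensor errors.

Kinematic model
---------------
The forearm is a rigid pendulum of length ``arm_length`` hanging from a
shoulder that translates at the commanded walking speed along the heading
``psi(t)``.  The swing angle about the horizontal axis perpendicular to
the heading is

    theta(t) = A(v) * sin(phi(t)),      A(v) = swing_gain * v
    phi'(t)  = 2*pi * f(v),             f(v) = base_step_freq + freq_gain * v

with ``v`` the walking speed in m/s and ``f`` the stride (arm-swing)
frequency.  The forearm orientation is ``R_nf = Rz(psi) @ Ry(theta)`` and
the sensor is attached through a fixed mount rotation.  Orientation,
body angular rate, and wrist specific force are evaluated in closed form
(the swing term is the exact second derivative of the pendulum tip
position), so the simulator doubles as an oracle for the orientation
filter and the gravity-compensation step.

Gait oscillation of the shoulder is modeled at twice the stride
frequency (one impulse per step): a fore-aft and a vertical component
whose displacement amplitudes scale with the swing amplitude.

Each trial starts with a standstill lead-in (default 2 s) emulating the
subject standing before walking; epoch labels are computed from the end
of the lead-in (``ImuRecording.analysis_start``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from wristspeed.frames import G_UP, GRAVITY, MAG_FIELD, quats_from_rotation
from wristspeed.recording import ImuRecording

EPOCH_SECONDS = 5.0

# displacement amplitude of the gait oscillation, metres per radian of
# swing amplitude (fore-aft and vertical); see module docstring
FORWARD_OSC_GAIN = 0.02
BOB_GAIN = 0.03
# heel-strike transients: broadband (2.5-12 Hz), vertical-dominated
# acceleration whose RMS scales like the gait oscillation
IMPACT_GAIN = 0.02


@dataclass
class NoiseSpec:
    """Additive sensor-error model (white noise + constant gyro bias)."""

    acc_noise_sd: float = 0.05   # m/s^2
    gyro_noise_sd: float = 0.005  # rad/s
    gyro_bias: np.ndarray | None = None  # rad/s; drawn ~N(0, bias_sd) if None
    gyro_bias_sd: float = 0.01   # rad/s, used when gyro_bias is None
    mag_noise_sd: float = 0.02   # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("acc_noise_sd", "gyro_noise_sd", "mag_noise_sd",
                     "gyro_bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gyro_bias is not None:
            self.gyro_bias = np.asarray(self.gyro_bias, dtype=float)
            if self.gyro_bias.shape != (3,):
                raise ValueError("gyro_bias must be a 3-vector")

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseSpec":
        """Noise-free spec (zero SDs and zero bias) for oracle tests."""
        return cls(0.0, 0.0, np.zeros(3), 0.0, 0.0, seed)


@dataclass
class SubjectProfile:
    """Anthropometry and arm-swing style of one simulated subject."""

    subject_id: str = "S00"
    height: float = 1.69          # m
    weight: float = 65.0          # kg
    arm_length: float = 0.7       # m, shoulder-to-wrist pendulum length
    swing_gain: float = 0.3       # rad per (m/s): amplitude-speed coupling
    base_step_freq: float = 0.6   # Hz, stride frequency at v -> 0
    freq_gain: float = 0.4        # Hz per (m/s): frequency-speed coupling
    mount_rotation: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0])
    )  # scalar-first unit quaternion, sensor frame -> forearm frame
    swing_harmonic: float = 0.25  # relative 2nd-harmonic content of the swing
    harmonic_phase: float = 1.0   # rad, phase of the 2nd harmonic

    def __post_init__(self) -> None:
        if not 1.4 <= self.height <= 2.0:
            raise ValueError("height must be in [1.4, 2.0] m")
        if not 40.0 <= self.weight <= 120.0:
            raise ValueError("weight must be in [40, 120] kg")
        if self.arm_length <= 0:
            raise ValueError("arm_length must be positive")
        if self.swing_gain < 0:
            raise ValueError("swing_gain must be >= 0")
        q = np.asarray(self.mount_rotation, dtype=float)
        if q.shape != (4,) or abs(np.linalg.norm(q) - 1.0) > 1e-6:
            raise ValueError("mount_rotation must be a unit quaternion")
        self.mount_rotation = q / np.linalg.norm(q)


@dataclass
class TrialPlan:
    """Speed/heading schedule for one trial.

    ``segments`` is a sequence of ``(duration_s, speed_cm_s)`` pairs; the
    speed profile is piecewise constant.  ``heading`` is either a constant
    yaw (rad) or a callable ``t -> yaw``.  A standstill ``lead_in``
    precedes the first segment.
    """

    segments: Sequence[tuple[float, float]]
    heading: float | Callable[[np.ndarray], np.ndarray] = 0.0
    sample_rate: float = 100.0
    lead_in: float = 2.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    speed_limits: tuple[float, float] = (50.0, 200.0)  # cm/s
    #: stride-time variability (CV of instantaneous stride frequency);
    #: healthy gait shows a few percent.  Phase jitter broadens spectral
    #: peaks, twice as much for frequency-doubled components.
    timing_jitter: float = 0.03

    def __post_init__(self) -> None:
        self.segments = [(float(d), float(v)) for d, v in self.segments]
        if not self.segments:
            raise ValueError("at least one speed segment is required")
        for d, v in self.segments:
            if not np.isfinite(d) or not np.isfinite(v) or d <= 0:
                raise ValueError("segment durations must be finite and > 0")
            lo, hi = self.speed_limits
            if not lo <= v <= hi:
                raise ValueError(
                    f"speed {v} cm/s outside allowed range [{lo}, {hi}]"
                )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.walk_duration < EPOCH_SECONDS:
            raise ValueError("plan must cover at least one 5-s epoch")
        if self.lead_in < 0:
            raise ValueError("lead_in must be >= 0")

    @property
    def walk_duration(self) -> float:
        return float(sum(d for d, _ in self.segments))

    @property
    def duration(self) -> float:
        return self.lead_in + self.walk_duration

    def speed_at(self, t: np.ndarray) -> np.ndarray:
        """Ground-truth speed (m/s) at times ``t`` (0 during lead-in)."""
        t = np.asarray(t, dtype=float)
        v = np.zeros_like(t)
        edges = self.lead_in + np.concatenate(
            [[0.0], np.cumsum([d for d, _ in self.segments])]
        )
        for k, (_, sp) in enumerate(self.segments):
            mask = (t >= edges[k] - 1e-12) & (t < edges[k + 1] - 1e-12)
            v[mask] = sp / 100.0
        v[t >= edges[-1] - 1e-12] = self.segments[-1][1] / 100.0
        v[t < self.lead_in - 1e-12] = 0.0
        return v


@dataclass
class TrialTruth:
    """Analytic ground truth emitted alongside a simulated recording."""

    quaternions: np.ndarray   # (N, 4) scalar-first, s-frame -> n-frame
    omega_s: np.ndarray       # (N, 3) true body rate, rad/s
    a_ext_n: np.ndarray       # (N, 3) true external acceleration, n-frame
    speed: np.ndarray         # (N,) true speed, m/s
    epoch_speeds: np.ndarray  # (E,) mean speed per 5-s epoch, cm/s
    gyro_bias: np.ndarray     # (3,) bias actually applied


def _segment_kinematics(plan: TrialPlan, profile: SubjectProfile,
                        t: np.ndarray):
    """Per-sample swing angle/rates and swing phase, piecewise by segment.

    The phase restarts at zero at each segment boundary so the swing angle
    enters every segment continuously at theta = 0.  Stride-time
    variability is modeled as a slow sinusoidal frequency modulation
    (a few components below 0.4 Hz, drawn from the trial seed), which
    keeps the phase and all its derivatives in closed form.
    """
    theta = np.zeros_like(t)
    dtheta = np.zeros_like(t)
    ddtheta = np.zeros_like(t)
    phase = np.zeros_like(t)
    dphase = np.zeros_like(t)
    freq = np.full_like(t, profile.base_step_freq)
    envelope = np.zeros_like(t)
    edges = plan.lead_in + np.concatenate(
        [[0.0], np.cumsum([d for d, _ in plan.segments])]
    )
    jit_rng = np.random.default_rng(
        np.random.SeedSequence(plan.noise.seed, spawn_key=(77,))
    )
    n_jit = 4
    for k, (dur, sp) in enumerate(plan.segments):
        v = sp / 100.0
        lo, hi = edges[k], edges[k + 1]
        mask = (t >= lo - 1e-12) & (t < hi - 1e-12)
        if k == len(plan.segments) - 1:
            mask |= t >= hi - 1e-12
        f = profile.base_step_freq + profile.freq_gain * v
        a = profile.swing_gain * v
        w = 2.0 * np.pi * f
        tau = t[mask] - lo

        # jittered phase: phi = w * (tau + integral of eps), with eps a
        # sum of slow sinusoids of total SD plan.timing_jitter
        nu = jit_rng.uniform(0.05, 0.4, size=n_jit)
        rho = jit_rng.uniform(0.0, 2.0 * np.pi, size=n_jit)
        amp_j = plan.timing_jitter * np.sqrt(2.0 / n_jit)
        arg = 2.0 * np.pi * nu[:, None] * tau[None, :] + rho[:, None]
        eps = amp_j * np.sin(arg).sum(axis=0)
        int_eps = (amp_j / (2.0 * np.pi * nu[:, None])
                   * (np.cos(rho)[:, None] - np.cos(arg))).sum(axis=0)
        deps = (amp_j * 2.0 * np.pi * nu[:, None] * np.cos(arg)).sum(axis=0)
        ph = w * (tau + int_eps)
        dph = w * (1.0 + eps)
        ddph = w * deps

        # raised-cosine amplitude onset over the first second of the
        # segment: keeps theta and theta' continuous at the walk onset
        # (an instantaneous swing start would put a step into the gyro)
        r = min(1.0, dur / 2.0)
        e = np.where(tau < r, 0.5 * (1 - np.cos(np.pi * tau / r)), 1.0)
        de = np.where(
            tau < r, 0.5 * np.pi / r * np.sin(np.pi * tau / r), 0.0
        )
        dde = np.where(
            tau < r, 0.5 * (np.pi / r) ** 2 * np.cos(np.pi * tau / r), 0.0
        )

        # asymmetric pendular swing: fundamental plus a second harmonic
        # (real arm swing is not sinusoidal; the harmonic content is what
        # makes the spectral speed signature well resolved)
        h, dl = profile.swing_harmonic, profile.harmonic_phase
        s = np.sin(ph) + h * np.sin(2.0 * ph + dl)
        ds = np.cos(ph) + 2.0 * h * np.cos(2.0 * ph + dl)
        dds = -np.sin(ph) - 4.0 * h * np.sin(2.0 * ph + dl)
        theta[mask] = a * e * s
        dtheta[mask] = a * (de * s + e * ds * dph)
        ddtheta[mask] = a * (
            dde * s + 2.0 * de * ds * dph
            + e * (dds * dph**2 + ds * ddph)
        )
        phase[mask] = ph
        dphase[mask] = dph
        freq[mask] = f
        envelope[mask] = e
    return theta, dtheta, ddtheta, phase, dphase, freq, envelope


def simulate_trial(
    profile: SubjectProfile,
    plan: TrialPlan,
    trial_id: str = "trial",
    forward_osc_gain: float = FORWARD_OSC_GAIN,
    bob_gain: float = BOB_GAIN,
    osc_phase: float = 0.0,
    impact_gain: float = IMPACT_GAIN,
) -> tuple[ImuRecording, TrialTruth]:
    """Simulate one walking trial; return the recording and its truth.

    The accelerometer emits ``R_ns^T @ (a_ext_n + G_UP) + noise``, the
    gyroscope the true body rate plus bias and noise, and the
    magnetometer ``R_ns^T @ MAG_FIELD + noise``.
    """
    # aliasing guard for the downstream 20 Hz low-pass stage
    if plan.sample_rate <= 2 * 20.0:
        raise ValueError("sample_rate must exceed twice the 20 Hz cutoff")

    fs = plan.sample_rate
    n = int(round(plan.duration * fs))
    t = np.arange(n) / fs
    v = plan.speed_at(t)

    # heading and its time derivatives (exact zeros for constant heading)
    if callable(plan.heading):
        psi = np.asarray(plan.heading(t), dtype=float).copy()
        if psi.shape != t.shape:
            raise ValueError("heading callable must be vectorized over t")
        # the subject stands still during the lead-in: heading changes
        # model walking-path curvature and only start at the walk onset
        i_start = int(round(plan.lead_in * fs))
        if i_start > 0 and i_start < n:
            psi[:i_start] = psi[i_start]
        dpsi = np.gradient(psi, t)
        ddpsi = np.gradient(dpsi, t)
    else:
        psi = np.full_like(t, float(plan.heading))
        dpsi = np.zeros_like(t)
        ddpsi = np.zeros_like(t)
    if not np.all(np.isfinite(psi)):
        raise ValueError("non-finite heading profile")

    (theta, dtheta, ddtheta, phase, dphase, freq,
     envelope) = _segment_kinematics(plan, profile, t)

    c, s = np.cos(psi), np.sin(psi)
    ct, st = np.cos(theta), np.sin(theta)

    # pendulum tip u = (st*c, st*s, ct); wrist at p_shoulder - L*u... the
    # sensor hangs below the shoulder, so p_wrist = p_sh + L*(-u) and the
    # swing contribution to wrist acceleration is -L * u''.
    dd_u1 = ((ct * ddtheta - st * dtheta**2) * c
             - 2.0 * ct * dtheta * s * dpsi
             - st * c * dpsi**2 - st * s * ddpsi)
    dd_u2 = ((ct * ddtheta - st * dtheta**2) * s
             + 2.0 * ct * dtheta * c * dpsi
             - st * s * dpsi**2 + st * c * ddpsi)
    dd_u3 = -ct * dtheta**2 - st * ddtheta
    swing_acc = -profile.arm_length * np.column_stack([dd_u1, dd_u2, dd_u3])

    # shoulder: centripetal term from heading change + gait oscillation at
    # twice the stride frequency (one impulse per step)
    amp = profile.swing_gain * v * envelope
    w2 = 2.0 * np.pi * 2.0 * freq
    osc_fwd = (forward_osc_gain * amp * w2**2
               * np.sin(2.0 * phase + osc_phase))
    osc_up = (bob_gain * amp * w2**2
              * np.cos(2.0 * phase + osc_phase))
    shoulder_acc = np.column_stack(
        [
            v * dpsi * (-s) + osc_fwd * c,
            v * dpsi * c + osc_fwd * s,
            osc_up,
        ]
    )
    a_ext_n = swing_acc + shoulder_acc

    # heel-strike transients: real wrist acceleration carries broadband,
    # vertical-dominated impact content that the norm variables fold into
    # their spectra while a horizontal principal-axis projection largely
    # rejects it.  Band-limited (2.5-12 Hz) seeded noise, RMS scaling
    # with the gait oscillation.
    if impact_gain > 0.0:
        from scipy import signal as _signal

        imp_rng = np.random.default_rng(
            np.random.SeedSequence(plan.noise.seed, spawn_key=(88,))
        )
        white = imp_rng.standard_normal((n, 3))
        hi_cut = min(12.0, 0.45 * fs)
        sos = _signal.butter(2, [2.5, hi_cut], btype="bandpass", fs=fs,
                             output="sos")
        band = _signal.sosfilt(sos, white, axis=0)
        band /= max(band.std(), 1e-12)
        scale = impact_gain * amp * w2**2
        fwd_n, lat_n, up_n = (band * np.array([0.35, 0.35, 1.0])).T
        # impact directions ride with the walking direction
        a_ext_n += scale[:, None] * np.column_stack(
            [
                fwd_n * c - lat_n * s,
                fwd_n * s + lat_n * c,
                up_n,
            ]
        )

    # orientation: R_ns = Rz(psi) @ Ry(theta) @ R_mount
    rot_nf = Rotation.from_euler("ZY", np.column_stack([psi, theta]))
    rot_mount = Rotation.from_quat(profile.mount_rotation, scalar_first=True)
    rot_ns = rot_nf * rot_mount
    quats = quats_from_rotation(rot_ns)

    # body rate of Rz(psi)@Ry(theta): omega_f = (-dpsi*st, dtheta, dpsi*ct)
    omega_f = np.column_stack([-dpsi * st, dtheta, dpsi * ct])
    omega_s = rot_mount.inv().apply(omega_f)

    rng = np.random.default_rng(plan.noise.seed)
    bias = plan.noise.gyro_bias
    if bias is None:
        bias = rng.normal(0.0, plan.noise.gyro_bias_sd, size=3)

    acc = rot_ns.inv().apply(a_ext_n + G_UP)
    mag = rot_ns.inv().apply(np.tile(MAG_FIELD, (n, 1)))
    acc = acc + rng.normal(0.0, plan.noise.acc_noise_sd, size=(n, 3))
    gyro = omega_s + bias + rng.normal(0.0, plan.noise.gyro_noise_sd, (n, 3))
    mag = mag + rng.normal(0.0, plan.noise.mag_noise_sd, size=(n, 3))

    # per-epoch ground truth, epochs anchored at the end of the lead-in
    epoch_len = int(round(EPOCH_SECONDS * fs))
    i0 = int(round(plan.lead_in * fs))
    n_epochs = (n - i0) // epoch_len
    epoch_speeds = np.array(
        [
            100.0 * v[i0 + k * epoch_len: i0 + (k + 1) * epoch_len].mean()
            for k in range(n_epochs)
        ]
    )

    rec = ImuRecording(
        timestamps=t,
        acc=acc,
        gyro=gyro,
        mag=mag,
        sample_rate=fs,
        trial_id=trial_id,
        subject_id=profile.subject_id,
        height=profile.height,
        weight=profile.weight,
        analysis_start=plan.lead_in,
    )
    truth = TrialTruth(
        quaternions=quats,
        omega_s=omega_s,
        a_ext_n=a_ext_n,
        speed=v,
        epoch_speeds=epoch_speeds,
        gyro_bias=np.asarray(bias, dtype=float),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# cohort generation

#: walking-speed regimes, cm/s (lower-inclusive; fast closed at 200)
REGIMES = {"slow": (50.0, 100.0), "normal": (100.0, 150.0),
           "fast": (150.0, 200.0)}


def sample_subject(subject_id: str, rng: np.random.Generator) -> SubjectProfile:
    """Draw one subject around the cohort means (height 1.69±0.08 m,
    weight 65±10 kg) with individual arm-swing style and a random
    sensor-on-wrist mounting misalignment of up to ~15 degrees.

    Gait timing is anthropometry-coupled, as in real cohorts: arm length
    scales with height, and the stride frequency follows pendulum scaling
    (longer limbs swing slower) with an individual residual.  Swing
    *amplitude* style, in contrast, varies freely between subjects — this
    is the component of wrist kinematics that anthropometry does not
    explain.
    """
    height = float(np.clip(rng.normal(1.69, 0.08), 1.4, 2.0))
    weight = float(np.clip(rng.normal(65.0, 10.0), 40.0, 120.0))
    arm = float(np.clip(0.41 * height + rng.normal(0.0, 0.01), 0.5, 0.9))
    base = 0.6 * np.sqrt(0.41 * 1.69 / arm) + rng.normal(0.0, 0.015)
    angle = rng.uniform(0.0, np.deg2rad(15.0))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    mount = Rotation.from_rotvec(angle * axis).as_quat(scalar_first=True)
    return SubjectProfile(
        subject_id=subject_id,
        height=height,
        weight=weight,
        arm_length=arm,
        swing_gain=float(np.clip(rng.normal(0.3, 0.05), 0.1, 0.6)),
        base_step_freq=float(np.clip(base, 0.4, 0.9)),
        freq_gain=float(np.clip(rng.normal(0.4, 0.015), 0.2, 0.6)),
        mount_rotation=mount,
        swing_harmonic=float(np.clip(rng.normal(0.25, 0.05), 0.05, 0.5)),
        harmonic_phase=float(rng.normal(1.0, 0.3)),
    )


def make_cohort(
    n_subjects: int = 15,
    trials_per_regime: int = 4,
    trial_duration: float = 25.0,
    seed: int = 0,
    noise: NoiseSpec | None = None,
    heading_wander: float = 0.1,
) -> list[tuple[SubjectProfile, list[tuple[ImuRecording, TrialTruth]]]]:
    """Simulate a cohort mirroring the study protocol: each subject walks
    steady-speed trials in three self-selected regimes (slow 50–100,
    normal 100–150, fast 150–200 cm/s), ``trials_per_regime`` each.

    Each trial has a random constant base heading plus a slow sinusoidal
    heading wander of amplitude ``heading_wander`` rad.  All randomness
    derives from ``seed`` via independent spawned streams.
    """
    root = np.random.SeedSequence(seed)
    cohort = []
    for si, ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(ss)
        profile = sample_subject(f"S{si:02d}", rng)
        # how strongly the gait impulse transmits to the wrist varies
        # with build and posture; it is not a universal constant
        fwd_gain = float(np.clip(
            rng.normal(FORWARD_OSC_GAIN, 0.006), 0.005, 0.05))
        bob = float(np.clip(rng.normal(BOB_GAIN, 0.009), 0.01, 0.08))
        phase = float(rng.uniform(0.0, 2.0 * np.pi))
        impact = float(np.clip(
            rng.normal(IMPACT_GAIN, 0.3 * IMPACT_GAIN),
            0.2 * IMPACT_GAIN, 3.0 * IMPACT_GAIN))
        trials = []
        ti = 0
        for regime, (lo, hi) in REGIMES.items():
            for _ in range(trials_per_regime):
                speed = rng.uniform(lo + 5.0, hi - 5.0)
                base = rng.uniform(-np.pi, np.pi)
                wander_period = rng.uniform(12.0, 25.0)
                wander_phase = rng.uniform(0.0, 2 * np.pi)

                def heading(t, b=base, p=wander_period, ph=wander_phase):
                    return b + heading_wander * np.sin(
                        2 * np.pi * t / p + ph
                    )

                base_noise = noise if noise is not None else NoiseSpec()
                trial_noise = NoiseSpec(
                    acc_noise_sd=base_noise.acc_noise_sd,
                    gyro_noise_sd=base_noise.gyro_noise_sd,
                    gyro_bias=base_noise.gyro_bias,
                    gyro_bias_sd=base_noise.gyro_bias_sd,
                    mag_noise_sd=base_noise.mag_noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                plan = TrialPlan(
                    segments=[(trial_duration, speed)],
                    heading=heading,
                    noise=trial_noise,
                )
                trial_id = f"{profile.subject_id}_T{ti:02d}_{regime}"
                trials.append(
                    simulate_trial(
                        profile, plan, trial_id,
                        forward_osc_gain=fwd_gain, bob_gain=bob,
                        osc_phase=phase, impact_gain=impact,
                    )
                )
                ti += 1
        cohort.append((profile, trials))
    return cohort


# ---------------------------------------------------------------------------
# on-disk export

def write_trial(rec: ImuRecording, truth: TrialTruth, out_dir: str | Path,
                fmt: str = "csv") -> Path:
    """Write one trial (CSV or HDF5) plus nothing else; see
    :func:`write_manifest` for the label sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        path = out_dir / f"{rec.trial_id}.csv"
        rec.to_csv(path)
    elif fmt == "hdf5":
        path = out_dir / "trials.h5"
        rec.to_hdf5(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def write_manifest(
    cohort, out_dir: str | Path, filename: str = "manifest.yaml"
) -> Path:
    """YAML manifest with per-trial metadata and ground-truth epoch speeds."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for profile, trials in cohort:
        for rec, truth in trials:
            entries.append(
                {
                    "trial_id": rec.trial_id,
                    "subject_id": profile.subject_id,
                    "height_m": round(profile.height, 4),
                    "weight_kg": round(profile.weight, 2),
                    "sample_rate_hz": rec.sample_rate,
                    "analysis_start_s": rec.analysis_start,
                    "epoch_speeds_cm_s": [
                        round(float(x), 3) for x in truth.epoch_speeds
                    ],
                }
            )
    path = out_dir / filename
    with open(path, "w") as f:
        yaml.safe_dump({"trials": entries}, f, sort_keys=False)
    return path
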