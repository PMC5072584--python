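"""Orientation estimation from 9-axis IMU data.

The estimator is an error-state quaternion Kalman filter of the standard
MARG-fusion family: gyroscope propagation at the sample rate, a gravity
(accelerometer) measurement update gated to quasi-static samples, and a
magnetometer update that corrects heading only.  The error state is the
3-vector attitude error (body frame, right-multiplicative) plus a 3-vector
gyro bias.

Attitude is initialized with the TRIAD solution on the first quasi-static
window: the mean accelerometer fixes "up", the horizontal projection of
the mean magnetometer fixes "north".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from wristspeed.frames import (
    G_UP,
    GRAVITY,
    quat_from_rotvec,
    quat_multiply,
    quat_to_matrix,
    rotation_from_quats,
    skew,
)
from wristspeed.recording import ImuRecording


@dataclass
class FilterParams:
    """Tunings of the error-state Kalman filter (unitless defaults)."""

    q_gyro: float = 1e-4        # attitude process noise density
    q_bias: float = 1e-8        # gyro-bias random-walk density
    r_acc: float = 1e-1         # gravity-direction measurement variance
    r_mag: float = 1e-1         # heading measurement variance (rad^2)
    acc_gate: float = 0.5       # m/s^2; accept accel update when ||a|-g| < gate
    omega_ref: float = 0.01     # rad/s; r_acc inflates by (1 + (rate/ref)^2)
    rate_hold_tau: float = 1.0  # s; decay time of the gyro-rate peak-hold
    init_window: float = 0.5    # s of data used for TRIAD initialization
    use_acc_update: bool = True
    use_mag_update: bool = True


@dataclass
class OrientationSeries:
    """Per-sample unit quaternions mapping the sensor frame to the n-frame."""

    timestamps: np.ndarray
    quaternions: np.ndarray  # (N, 4) scalar-first

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        if self.quaternions.shape != (len(self.timestamps), 4):
            raise ValueError("quaternions must be (N, 4)")
        norms = np.linalg.norm(self.quaternions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternions must have unit norm")

    def rotation(self) -> np.ndarray:
        """(N, 3, 3) rotation matrices R_s->n."""
        return rotation_from_quats(self.quaternions).as_matrix()

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            np.column_stack([self.timestamps, self.quaternions]),
            columns=["t", "qw", "qx", "qy", "qz"],
        ).to_csv(path, index=False)


def triad(acc_mean: np.ndarray, mag_mean: np.ndarray) -> np.ndarray:
    """TRIAD attitude from mean specific force and magnetic field.

    Returns the scalar-first quaternion of ``R_s->n`` built from the
    up direction (accelerometer) and horizontal north (magnetometer).
    """
    up = acc_mean / np.linalg.norm(acc_mean)
    horiz = mag_mean - np.dot(mag_mean, up) * up
    h = np.linalg.norm(horiz)
    if h < 1e-12:
        raise ValueError("magnetometer parallel to gravity: heading unobservable")
    north = horiz / h
    west = np.cross(up, north)
    # rows of R_ns are the n-frame axes expressed in sensor coordinates
    r_ns = np.vstack([north, west, up])
    from scipy.spatial.transform import Rotation

    q = Rotation.from_matrix(r_ns).as_quat(scalar_first=True)
    return q if q[0] >= 0 else -q


def initialize_attitude(acc_window: np.ndarray, mag_window: np.ndarray
                        ) -> np.ndarray:
    """TRIAD initialization from a quasi-static window.

    Raises ``ValueError`` when the window is clearly not static (mean
    accelerometer norm off |g| by more than 20 %).
    """
    acc_window = np.atleast_2d(np.asarray(acc_window, dtype=float))
    mag_window = np.atleast_2d(np.asarray(mag_window, dtype=float))
    acc_mean = acc_window.mean(axis=0)
    mag_mean = mag_window.mean(axis=0)
    norm = np.linalg.norm(acc_mean)
    if abs(norm - GRAVITY) > 0.2 * GRAVITY:
        raise ValueError(
            f"window not static: mean |acc| = {norm:.2f} m/s^2"
        )
    return triad(acc_mean, mag_mean)


def estimate_orientation(
    rec: ImuRecording,
    params: FilterParams | None = None,
    initial_quaternion: np.ndarray | None = None,
) -> OrientationSeries:
    """Run the error-state Kalman filter over a recording.

    Deterministic for a fixed input and parameter set.  Raises on
    non-finite samples and on vanishing accelerometer/magnetometer norms
    (attitude unobservable).
    """
    params = params or FilterParams()
    rec.validate()
    acc, gyro, mag = rec.acc, rec.gyro, rec.mag
    if np.any(np.linalg.norm(acc, axis=1) < 1e-9):
        raise ValueError("all-zero accelerometer sample: attitude unobservable")
    if np.any(np.linalg.norm(mag, axis=1) < 1e-9):
        raise ValueError("all-zero magnetometer sample: heading unobservable")
    n = rec.n_samples
    fs = rec.sample_rate
    if n < fs:
        raise ValueError("need at least 1 s of data for initialization")
    dt = 1.0 / fs

    n_init = max(2, int(round(params.init_window * fs)))
    if initial_quaternion is not None:
        q = np.asarray(initial_quaternion, dtype=float).copy()
        p_att0 = 1e-4
        bias = np.zeros(3)
    else:
        try:
            q = initialize_attitude(acc[:n_init], mag[:n_init])
            p_att0 = 1e-3
            # static window: gyro mean is the bias
            bias = gyro[:n_init].mean(axis=0)
        except ValueError:
            # moving from the first sample: TRIAD on the means anyway,
            # with inflated attitude uncertainty so updates pull it in
            q = triad(acc[:n_init].mean(axis=0), mag[:n_init].mean(axis=0))
            p_att0 = 0.5
            bias = np.zeros(3)

    quats = np.empty((n, 4))
    rate_hold = 0.0
    hold_decay = float(np.exp(-dt / params.rate_hold_tau))
    p = np.diag([p_att0] * 3 + [1e-4] * 3)
    q_noise = np.diag([params.q_gyro * dt] * 3 + [params.q_bias * dt] * 3)
    i6 = np.eye(6)

    for k in range(n):
        if k > 0:
            # --- propagate (midpoint rule on the gyro samples) -----------
            omega = 0.5 * (gyro[k - 1] + gyro[k]) - bias
            q = quat_multiply(q, quat_from_rotvec(omega * dt))
            q /= np.linalg.norm(q)
            f = i6.copy()
            f[:3, :3] = np.eye(3) - skew(omega) * dt
            f[:3, 3:] = -np.eye(3) * dt
            p = f @ p @ f.T + q_noise

        r = quat_to_matrix(q)
        delta = np.zeros(6)
        updated = False

        # --- gravity update (gated external-acceleration rejection) ------
        a = acc[k]
        a_norm = np.linalg.norm(a)
        if params.use_acc_update and abs(a_norm - GRAVITY) < params.acc_gate:
            g_pred = r.T @ np.array([0.0, 0.0, 1.0])  # unit up in s-frame
            z = a / a_norm - g_pred
            h = np.zeros((3, 6))
            h[:, :3] = skew(g_pred)
            # a norm close to |g| does not preclude a large external
            # acceleration perpendicular to gravity; distrust the gravity
            # direction while the sensor is moving.  The activity measure
            # is a decaying peak-hold of the gyro rate, not the
            # instantaneous rate: at swing reversals the rate passes
            # through zero while the external acceleration is largest.
            rate = np.linalg.norm(gyro[k] - bias)
            rate_hold = max(rate, rate_hold * hold_decay)
            r_eff = params.r_acc * (1.0 + (rate_hold / params.omega_ref) ** 2)
            s_mat = h @ p @ h.T + r_eff * np.eye(3)
            k_gain = p @ h.T @ np.linalg.solve(s_mat, np.eye(3))
            delta = delta + k_gain @ z
            p = (i6 - k_gain @ h) @ p
            updated = True

        # --- heading update (yaw only) ------------------------------------
        if params.use_mag_update:
            m_s = mag[k]
            m_n = r @ m_s
            h_sq = m_n[0] ** 2 + m_n[1] ** 2
            if h_sq > 1e-12:
                # measured heading error of the horizontal field vs north
                y = np.arctan2(m_n[1], m_n[0])
                jac_v = np.array([-m_n[1], m_n[0], 0.0]) / h_sq
                h_row = (-(jac_v @ r) @ skew(m_s)).reshape(1, 3)
                h = np.zeros((1, 6))
                h[0, :3] = h_row
                s_val = (h @ p @ h.T).item() + params.r_mag
                k_gain = (p @ h.T / s_val).ravel()
                delta = delta + k_gain * (-y)
                p = (i6 - np.outer(k_gain, h)) @ p
                updated = True

        if updated:
            q = quat_multiply(q, quat_from_rotvec(delta[:3]))
            q /= np.linalg.norm(q)
            bias = bias + delta[3:]

        quats[k] = q if q[0] >= 0 else -q

    return OrientationSeries(timestamps=rec.timestamps, quaternions=quats)


def attitude_error_deg(estimated: OrientationSeries,
                       true_quats: np.ndarray) -> np.ndarray:
    """Per-sample geodesic attitude error (degrees) vs a truth series."""
    est = estimated.quaternions
    dots = np.abs(np.sum(est * true_quats, axis=1))
    return np.degrees(2.0 * np.arccos(np.clip(dots, -1.0, 1.0)))
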