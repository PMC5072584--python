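"""Coordinate-frame conventions and small quaternion helpers.

Conventions used throughout the package (stated once, used everywhere):

* **n-frame** (navigation): right-handed local-level frame, ``z`` axis UP,
  ``x`` = magnetic north, ``y`` = west.  Gravity as a force points down,
  so the *specific force* measured by a static accelerometer is
  ``R_ns^T @ G_UP`` with ``G_UP = (0, 0, +9.81)`` m/s².
* **s-frame** (sensor): the IMU case frame.  Orientation quaternions map
  s-frame vectors into the n-frame, i.e. ``v_n = R(q) @ v_s``.
* Quaternions are stored scalar-first ``(w, x, y, z)`` with unit norm.
* The reference magnetic field is horizontal-north plus a downward
  vertical component; only its horizontal direction carries heading
  information, so the declination and dip magnitude are arbitrary.

The hot quaternion arithmetic is written out explicitly (it sits inside
per-sample filter loops); conversions that happen once per array go
through :class:`scipy.spatial.transform.Rotation`.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

GRAVITY = 9.81
#: specific-force contribution of gravity in the n-frame (z up)
G_UP = np.array([0.0, 0.0, GRAVITY])
#: reference magnetic field: unit horizontal north + 0.5 vertical (down)
MAG_FIELD = np.array([1.0, 0.0, -0.5])


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product ``p ⊗ q`` of scalar-first quaternions."""
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def quat_from_rotvec(rv: np.ndarray) -> np.ndarray:
    """Unit quaternion for a rotation vector (axis * angle, radians)."""
    angle = float(np.linalg.norm(rv))
    if angle < 1e-300:
        return np.array([1.0, 0.0, 0.0, 0.0])
    half = 0.5 * angle
    axis = rv / angle
    s = np.sin(half)
    return np.array([np.cos(half), s * axis[0], s * axis[1], s * axis[2]])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """3x3 rotation matrix of a scalar-first unit quaternion."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_conj(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_angle(p: np.ndarray, q: np.ndarray) -> float:
    """Geodesic angle (radians) between two unit quaternions."""
    dot = abs(float(np.dot(p, q)))
    return 2.0 * np.arccos(min(1.0, dot))


def rotation_from_quats(quats: np.ndarray) -> Rotation:
    """Vectorized scipy Rotation from an (N, 4) scalar-first array."""
    return Rotation.from_quat(np.atleast_2d(quats), scalar_first=True)


def quats_from_rotation(rot: Rotation) -> np.ndarray:
    """(N, 4) scalar-first array, sign-fixed to non-negative scalar part."""
    q = np.atleast_2d(rot.as_quat(scalar_first=True))
    flip = q[:, 0] < 0
    q[flip] *= -1.0
    return q


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix: ``skew(v) @ u == np.cross(v, u)``."""
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )
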