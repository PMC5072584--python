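"""The three scalar motion variables derived from a wrist recording.

* ``acc``     — per-sample Euclidean norm of the raw specific force.
* ``ext_acc`` — norm of the external (gravity-compensated) acceleration
                in the navigation frame: ``a_ext_n = R_sn @ a_s - g_n``.
* ``pca_acc`` — the horizontal components of ``a_ext_n`` projected, per
                5-s epoch, onto their first principal axis (the arm-swing
                direction).  Invariant to heading up to a global sign per
                window, which a deterministic skewness rule fixes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from wristspeed.frames import G_UP
from wristspeed.orientation import OrientationSeries
from wristspeed.recording import ImuRecording

_SKEW_TIE_TOL = 1e-12


@dataclass
class VariableStream:
    """One scalar time series derived from a recording."""

    kind: str                # "acc" | "ext_acc" | "pca_acc"
    timestamps: np.ndarray
    values: np.ndarray
    source_trial: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.timestamps.shape:
            raise ValueError("values and timestamps must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite variable values")
        if self.kind in ("acc", "ext_acc") and np.any(self.values < 0):
            raise ValueError(f"{self.kind} is a norm and must be >= 0")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "t": self.timestamps,
                "value": self.values,
                "kind": self.kind,
                "trial_id": self.source_trial,
            }
        ).to_csv(path, index=False)


@dataclass
class NavAccSeries:
    """External acceleration in the navigation frame, plus gravity used."""

    timestamps: np.ndarray
    a_ext_n: np.ndarray      # (N, 3)
    gravity: np.ndarray = None

    def __post_init__(self) -> None:
        if self.gravity is None:
            self.gravity = G_UP.copy()
        self.a_ext_n = np.asarray(self.a_ext_n, dtype=float)
        if self.a_ext_n.shape != (len(self.timestamps), 3):
            raise ValueError("a_ext_n must be (N, 3)")
        if not np.all(np.isfinite(self.a_ext_n)):
            raise ValueError("non-finite external acceleration")


def compute_acc(rec: ImuRecording) -> VariableStream:
    """Per-sample norm of the raw accelerometer signal."""
    return VariableStream(
        kind="acc",
        timestamps=rec.timestamps,
        values=np.linalg.norm(rec.acc, axis=1),
        source_trial=rec.trial_id,
    )


def compute_ext_acc(
    rec: ImuRecording, orient: OrientationSeries
) -> tuple[NavAccSeries, VariableStream]:
    """Gravity-compensated acceleration and its norm.

    ``a_ext_n = R_s->n @ a_s - g_n`` with gravity ``g_n = (0, 0, +9.81)``
    (z-up convention; the accelerometer measures specific force).
    """
    if len(orient.quaternions) != rec.n_samples:
        raise ValueError("orientation and recording lengths differ")
    r = orient.rotation()
    a_n = np.einsum("nij,nj->ni", r, rec.acc)
    a_ext = a_n - G_UP
    nav = NavAccSeries(timestamps=rec.timestamps, a_ext_n=a_ext)
    stream = VariableStream(
        kind="ext_acc",
        timestamps=rec.timestamps,
        values=np.linalg.norm(a_ext, axis=1),
        source_trial=rec.trial_id,
    )
    return nav, stream


def principal_axis_projection(horizontal: np.ndarray) -> np.ndarray:
    """Project a mean-centered (N, 2) horizontal series onto its first
    principal axis, with the sign fixed so the projection has
    non-negative skewness (ties: first nonzero sample positive)."""
    centered = horizontal - horizontal.mean(axis=0)
    cov = centered.T @ centered / max(len(centered) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    if evals[-1] < 1e-12:
        return None
    axis = evecs[:, -1]
    proj = centered @ axis
    sd = proj.std()
    skew = 0.0 if sd < 1e-300 else float(np.mean((proj / sd) ** 3))
    if abs(skew) > _SKEW_TIE_TOL:
        if skew < 0:
            proj = -proj
    else:
        nonzero = np.nonzero(np.abs(proj) > _SKEW_TIE_TOL)[0]
        if len(nonzero) and proj[nonzero[0]] < 0:
            proj = -proj
    return proj


def compute_pca_acc(
    nav: NavAccSeries,
    windows: Sequence[tuple[int, int]],
    source_trial: str = "",
) -> VariableStream:
    """Per-window PCA projection of the horizontal external acceleration.

    ``windows`` are (start, stop) sample-index pairs (typically the 5-s
    feature epochs).  Within each window the (x, y) components are
    mean-centered, the unit eigenvector of the larger eigenvalue of their
    2x2 covariance is found, and the centered series is projected onto
    it.  A degenerate window (no horizontal motion) yields zeros and a
    warning.  The output covers exactly the windowed samples.
    """
    if not windows:
        raise ValueError("at least one window is required")
    values = []
    times = []
    for start, stop in windows:
        if stop - start < 2:
            raise ValueError("window must contain at least 2 samples")
        horiz = nav.a_ext_n[start:stop, :2]
        proj = principal_axis_projection(horiz)
        if proj is None:
            warnings.warn(
                "degenerate horizontal covariance: emitting zero pca_acc",
                stacklevel=2,
            )
            proj = np.zeros(stop - start)
        values.append(proj)
        times.append(nav.timestamps[start:stop])
    return VariableStream(
        kind="pca_acc",
        timestamps=np.concatenate(times),
        values=np.concatenate(values),
        source_trial=source_trial,
    )
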