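"""Preprocessing and per-epoch feature extraction.

Raw IMU channels are zero-phase low-pass filtered (4th-order Butterworth,
20 Hz cutoff) before variable computation.  Variable streams are cut into
non-overlapping 5-s epochs; each epoch yields 8 time-domain statistics
and the first 40 single-sided FFT amplitude coefficients (512-point FFT,
bins 1–40, i.e. frequencies below 8 Hz at 100 Hz sampling — DC is
excluded because it duplicates the time-domain mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

EPOCH_SECONDS = 5.0
NFFT = 512
N_FD = 40
TD_NAMES = [
    "td_mean",
    "td_sd",
    "td_median",
    "td_mode",
    "td_mean_abs",
    "td_mean_crossings",
    "td_sma",
    "td_energy",
]
FD_NAMES = [f"fd_{k:02d}" for k in range(1, N_FD + 1)]
ANTHRO_NAMES = ["height", "weight"]


def lowpass_filter(
    data: np.ndarray,
    sample_rate: float,
    cutoff: float = 20.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (DC gain exactly 1).

    Applied forward-backward (``sosfiltfilt``) so epoch boundaries stay
    aligned with the ground-truth timeline.  Works on 1-D signals or
    (N, C) channel stacks.
    """
    if sample_rate <= 2 * cutoff:
        raise ValueError("sample_rate must exceed twice the cutoff")
    data = np.asarray(data, dtype=float)
    sos = signal.butter(order, cutoff, btype="low", fs=sample_rate,
                        output="sos")
    padlen = 3 * (2 * order + 1)
    if data.shape[0] <= padlen:
        raise ValueError(
            f"signal too short for zero-phase filtering (need > {padlen})"
        )
    return signal.sosfiltfilt(sos, data, axis=0)


def epoch_split(
    values: np.ndarray,
    sample_rate: float,
    epoch_seconds: float = EPOCH_SECONDS,
    start: int = 0,
    overlap: float = 0.0,
) -> list[np.ndarray]:
    """Consecutive epochs (non-overlapping by default; ``overlap`` is the
    fraction of each window shared with the next); the trailing partial
    window is dropped."""
    values = np.asarray(values)
    return [
        values[a:b]
        for a, b in epoch_bounds(len(values), sample_rate, epoch_seconds,
                                 start, overlap)
    ]


def epoch_bounds(
    n_samples: int,
    sample_rate: float,
    epoch_seconds: float = EPOCH_SECONDS,
    start: int = 0,
    overlap: float = 0.0,
) -> list[tuple[int, int]]:
    """(start, stop) index pairs of the full epochs in a stream."""
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    epoch_len = int(round(epoch_seconds * sample_rate))
    step = max(1, int(round(epoch_len * (1.0 - overlap))))
    out = []
    a = start
    while a + epoch_len <= n_samples:
        out.append((a, a + epoch_len))
        a += step
    return out


def _histogram_mode(x: np.ndarray, bins: int = 50) -> float:
    """Mode of a continuous signal: center of the most populated of 50
    equal-width bins spanning the epoch range (ties -> lowest bin)."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-300:
        return lo
    counts, edges = np.histogram(x, bins=bins, range=(lo, hi))
    k = int(np.argmax(counts))
    return 0.5 * (edges[k] + edges[k + 1])


def mean_crossings(x: np.ndarray) -> int:
    """Sign changes of ``x - mean(x)``, zeros counted as positive."""
    s = np.where(x - np.mean(x) >= 0, 1, -1)
    return int(np.sum(s[1:] != s[:-1]))


def td_features(epoch: np.ndarray) -> np.ndarray:
    """The eight time-domain statistics, in :data:`TD_NAMES` order.

    SD is the sample standard deviation (ddof=1); signal magnitude area
    is ``sum(|x|)`` and energy ``sum(x**2)`` over the epoch.
    """
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("epoch must be a 1-D series of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in epoch")
    return np.array(
        [
            np.mean(x),
            np.std(x, ddof=1),
            np.median(x),
            _histogram_mode(x),
            np.mean(np.abs(x)),
            mean_crossings(x),
            np.sum(np.abs(x)),
            np.sum(x**2),
        ]
    )


def fd_features(
    epoch: np.ndarray,
    nfft: int = NFFT,
    n_coeffs: int = N_FD,
    include_dc: bool = False,
) -> np.ndarray:
    """Single-sided FFT amplitude coefficients of one epoch.

    The epoch is zero-padded to ``nfft`` points; amplitudes are
    ``2|X[k]| / N`` with ``N`` the pre-padding length.  Bin ``k`` maps to
    frequency ``k * fs / nfft`` (7.8125 Hz for bin 40 at 100 Hz).  DC is
    excluded by default (it duplicates the time-domain mean, up to the
    factor-2 single-sided convention).
    """
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch must be 1-D")
    if len(x) > nfft:
        raise ValueError(f"epoch longer than nfft={nfft}")
    spectrum = np.fft.rfft(x, n=nfft)
    amps = 2.0 * np.abs(spectrum) / len(x)
    first = 0 if include_dc else 1
    return amps[first: first + n_coeffs]


@dataclass
class EpochFeatures:
    """Feature vector of one 5-s epoch with its ground-truth speed."""

    trial_id: str
    subject_id: str
    epoch_index: int
    td: np.ndarray
    fd: np.ndarray
    label: float                  # ground-truth mean speed, cm/s
    height: float = float("nan")  # m
    weight: float = float("nan")  # kg

    def __post_init__(self) -> None:
        self.td = np.asarray(self.td, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        if self.td.shape != (len(TD_NAMES),):
            raise ValueError("td must have 8 entries")
        if self.fd.shape != (N_FD,):
            raise ValueError(f"fd must have {N_FD} entries")
        if self.td[1] < 0 or self.td[6] < 0 or self.td[7] < 0:
            raise ValueError("SD, SMA and energy must be >= 0")
        if np.any(self.fd < 0):
            raise ValueError("FD amplitudes must be >= 0")
        if not np.isnan(self.label) and self.label <= 0:
            raise ValueError("speed label must be positive")


def assemble_dataset(epochs: list[EpochFeatures]) -> pd.DataFrame:
    """Stack per-epoch features into a tidy DataFrame (one row per epoch).

    Columns: identifiers, the 8 TD features, 40 FD features, height,
    weight and the speed label; feature subsets for modeling are selected
    with :func:`design_matrix`.
    """
    if not epochs:
        return pd.DataFrame(
            columns=["subject_id", "trial_id", "epoch_index",
                     *TD_NAMES, *FD_NAMES, *ANTHRO_NAMES, "label"]
        )
    rows = []
    for ep in epochs:
        row = {
            "subject_id": ep.subject_id,
            "trial_id": ep.trial_id,
            "epoch_index": ep.epoch_index,
        }
        row.update(dict(zip(TD_NAMES, ep.td)))
        row.update(dict(zip(FD_NAMES, ep.fd)))
        row["height"] = ep.height
        row["weight"] = ep.weight
        row["label"] = ep.label
        rows.append(row)
    return pd.DataFrame(rows)


def feature_columns(include_fd: bool = True,
                    include_anthro: bool = False) -> list[str]:
    cols = list(TD_NAMES)
    if include_fd:
        cols += FD_NAMES
    if include_anthro:
        cols += ANTHRO_NAMES
    return cols


def design_matrix(
    dataset: pd.DataFrame,
    include_fd: bool = True,
    include_anthro: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, subject_ids) for regression from an assembled dataset."""
    if dataset["label"].isna().any():
        raise ValueError("missing speed labels")
    cols = feature_columns(include_fd, include_anthro)
    x = dataset[cols].to_numpy(dtype=float)
    y = dataset["label"].to_numpy(dtype=float)
    subjects = dataset["subject_id"].to_numpy()
    return x, y, subjects
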