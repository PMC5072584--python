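"""In-memory container and on-disk formats for 9-axis IMU recordings."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

CSV_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]


@dataclass
class ImuRecording:
    """Synchronized tri-axial accelerometer, gyroscope and magnetometer data.

    Parameters
    ----------
    timestamps : (N,) seconds, strictly increasing, nominally uniform.
    acc : (N, 3) specific force in the sensor frame, m/s².
    gyro : (N, 3) angular rate in the sensor frame, rad/s.
    mag : (N, 3) magnetic field in the sensor frame, arbitrary units.
    sample_rate : nominal sampling frequency, Hz.
    analysis_start : time (s) at which the walking portion begins; samples
        before it (a standstill lead-in) are used for filter initialization
        but excluded from epoching.
    """

    timestamps: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    sample_rate: float
    trial_id: str = ""
    subject_id: str = ""
    height: float = float("nan")
    weight: float = float("nan")
    analysis_start: float = 0.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        for name in ("acc", "gyro", "mag"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must be (N, 3), got {arr.shape}")
            setattr(self, name, arr)
        self.validate()

    def validate(self) -> None:
        n = len(self.timestamps)
        if not (len(self.acc) == len(self.gyro) == len(self.mag) == n):
            raise ValueError("sensor streams must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if n > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for name in ("timestamps", "acc", "gyro", "mag"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def analysis_index(self) -> int:
        """Index of the first sample at or after ``analysis_start``."""
        return int(np.searchsorted(self.timestamps, self.analysis_start - 1e-9))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.column_stack([self.timestamps, self.acc, self.gyro, self.mag]),
            columns=CSV_COLUMNS,
        )

    # --- CSV -----------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sample_rate: float | None = None,
                 **meta) -> "ImuRecording":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df.dropna()
        t = df["t"].to_numpy()
        if sample_rate is None:
            sample_rate = 1.0 / float(np.median(np.diff(t)))
        return cls(
            timestamps=t,
            acc=df[["ax", "ay", "az"]].to_numpy(),
            gyro=df[["gx", "gy", "gz"]].to_numpy(),
            mag=df[["mx", "my", "mz"]].to_numpy(),
            sample_rate=sample_rate,
            **meta,
        )

    # --- HDF5 (one group per trial) -----------------------------------
    def to_hdf5(self, path: str | Path, mode: str = "a") -> None:
        with h5py.File(path, mode) as f:
            grp = f.require_group(self.trial_id or "trial")
            for name in ("timestamps", "acc", "gyro", "mag"):
                if name in grp:
                    del grp[name]
                grp.create_dataset(name, data=getattr(self, name))
            grp.attrs["sample_rate"] = self.sample_rate
            grp.attrs["trial_id"] = self.trial_id
            grp.attrs["subject_id"] = self.subject_id
            grp.attrs["height"] = self.height
            grp.attrs["weight"] = self.weight
            grp.attrs["analysis_start"] = self.analysis_start

    @classmethod
    def from_hdf5(cls, path: str | Path, trial_id: str) -> "ImuRecording":
        with h5py.File(path, "r") as f:
            grp = f[trial_id]
            return cls(
                timestamps=grp["timestamps"][()],
                acc=grp["acc"][()],
                gyro=grp["gyro"][()],
                mag=grp["mag"][()],
                sample_rate=float(grp.attrs["sample_rate"]),
                trial_id=str(grp.attrs.get("trial_id", trial_id)),
                subject_id=str(grp.attrs.get("subject_id", "")),
                height=float(grp.attrs.get("height", float("nan"))),
                weight=float(grp.attrs.get("weight", float("nan"))),
                analysis_start=float(grp.attrs.get("analysis_start", 0.0)),
            )
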