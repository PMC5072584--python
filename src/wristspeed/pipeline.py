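"""End-to-end glue: recording -> orientation -> variable -> epoch features."""

from __future__ import annotations

import numpy as np
import pandas as pd

from wristspeed.features import (
    EPOCH_SECONDS,
    EpochFeatures,
    assemble_dataset,
    epoch_bounds,
    fd_features,
    lowpass_filter,
    td_features,
)
from wristspeed.orientation import FilterParams, estimate_orientation
from wristspeed.recording import ImuRecording
from wristspeed.variables import (
    compute_acc,
    compute_ext_acc,
    compute_pca_acc,
)

VARIABLE_KINDS = ("acc", "ext_acc", "pca_acc")


def preprocess(rec: ImuRecording) -> ImuRecording:
    """Low-pass filter all nine channels (20 Hz zero-phase Butterworth)."""
    return ImuRecording(
        timestamps=rec.timestamps,
        acc=lowpass_filter(rec.acc, rec.sample_rate),
        gyro=lowpass_filter(rec.gyro, rec.sample_rate),
        mag=lowpass_filter(rec.mag, rec.sample_rate),
        sample_rate=rec.sample_rate,
        trial_id=rec.trial_id,
        subject_id=rec.subject_id,
        height=rec.height,
        weight=rec.weight,
        analysis_start=rec.analysis_start,
    )


def variable_series(
    rec: ImuRecording,
    kind: str,
    filter_params: FilterParams | None = None,
    pca_scope: str = "epoch",
) -> tuple[list[np.ndarray], int]:
    """Per-epoch slices of the requested variable stream.

    Returns ``(epochs, n_epochs)`` where each epoch is one 5-s slice of
    the scalar variable, anchored at ``rec.analysis_start``.  Orientation
    estimation (needed for ``ext_acc`` / ``pca_acc``) runs over the full
    recording including the standstill lead-in so the fusion filter is
    converged when the walking portion begins.  ``pca_scope`` selects the
    support of the principal-axis estimate: one axis per 5-s epoch
    (default) or a single axis for the whole trial (``"trial"``).
    """
    if kind not in VARIABLE_KINDS:
        raise ValueError(f"unknown variable kind {kind!r}")
    filtered = preprocess(rec)
    bounds = epoch_bounds(
        rec.n_samples, rec.sample_rate, EPOCH_SECONDS, rec.analysis_index
    )
    if kind == "acc":
        stream = compute_acc(filtered)
        epochs = [stream.values[a:b] for a, b in bounds]
    else:
        orient = estimate_orientation(filtered, filter_params)
        nav, ext = compute_ext_acc(filtered, orient)
        if kind == "ext_acc":
            epochs = [ext.values[a:b] for a, b in bounds]
        else:
            if pca_scope == "trial":
                lo, hi = bounds[0][0], bounds[-1][1]
                stream = compute_pca_acc(nav, [(lo, hi)], rec.trial_id)
            elif pca_scope == "epoch":
                stream = compute_pca_acc(nav, bounds, rec.trial_id)
            else:
                raise ValueError(f"unknown pca_scope {pca_scope!r}")
            epoch_len = bounds[0][1] - bounds[0][0]
            epochs = [
                stream.values[k * epoch_len: (k + 1) * epoch_len]
                for k in range(len(bounds))
            ]
    return epochs, len(bounds)


def extract_trial_features(
    rec: ImuRecording,
    epoch_labels: np.ndarray,
    kind: str = "pca_acc",
    filter_params: FilterParams | None = None,
) -> list[EpochFeatures]:
    """Full feature extraction for one labeled trial."""
    epochs, n = variable_series(rec, kind, filter_params)
    epoch_labels = np.asarray(epoch_labels, dtype=float)
    if len(epoch_labels) < n:
        raise ValueError("fewer labels than epochs")
    return [
        EpochFeatures(
            trial_id=rec.trial_id,
            subject_id=rec.subject_id,
            epoch_index=k,
            td=td_features(ep),
            fd=fd_features(ep),
            label=float(epoch_labels[k]),
            height=rec.height,
            weight=rec.weight,
        )
        for k, ep in enumerate(epochs)
    ]


def cohort_dataset(
    cohort,
    kind: str = "pca_acc",
    filter_params: FilterParams | None = None,
) -> pd.DataFrame:
    """Assembled feature dataset for a simulated cohort
    (``[(profile, [(recording, truth), ...]), ...]``)."""
    feats: list[EpochFeatures] = []
    for _, trials in cohort:
        for rec, truth in trials:
            feats.extend(
                extract_trial_features(
                    rec, truth.epoch_speeds, kind, filter_params
                )
            )
    return assemble_dataset(feats)
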