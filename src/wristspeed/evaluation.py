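"""Evaluation protocol and error metrics for speed-estimation models.

Two modeling modes are compared:

* **generalized** — the model for subject *n* is trained on all epochs of
  the remaining subjects (leave-subject-out) and tested on a random 20 %
  sample of subject *n*'s epochs;
* **subject_specific** — trained on 80 % of subject *n*'s own epochs and
  tested on the held-out 20 %.

Both are repeated 10 times with freshly resampled test sets and the
errors averaged, first across repeats, then across subjects.  Accuracy is
reported as relative mean absolute error (MAE %) and RMSE in cm/s;
precision as the SD of the respective per-epoch error quantities (also
reported across subjects, labeled).  Agreement and correlation come from
Bland–Altman statistics and Pearson's r with a least-squares fit line;
method comparisons use one-way ANOVA on per-subject mean errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from wristspeed.features import design_matrix
from wristspeed.regression import GprModel, LassoModel, lasso_select_lambda

#: speed regimes in cm/s; lower-inclusive half-open, fast closed at 200
REGIMES = {
    "slow": (50.0, 100.0),
    "normal": (100.0, 150.0),
    "fast": (150.0, 200.0),
}


@dataclass
class ProtocolConfig:
    """Settings of one train/test experiment."""

    mode: str = "generalized"        # or "subject_specific"
    test_fraction: float = 0.2
    repeats: int = 10
    seed: int = 0
    variable_kind: str = "pca_acc"
    include_fd: bool = True
    include_anthro: bool | None = None   # default: only for generalized
    model: str = "gpr"               # or "lasso"
    train_speed_filter: tuple[float, float] | None = None  # cm/s interval
    gpr_restarts: int = 1
    gpr_max_iter: int = 150
    gpr_noise_floor: float = 0.15
    gpr_mean_function: str = "lasso"

    def __post_init__(self) -> None:
        if self.mode not in ("generalized", "subject_specific"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.include_anthro is None:
            # anthropometric features help models generalize across
            # subjects; they are constant within a subject
            self.include_anthro = self.mode == "generalized"


def _repeat_rng(master_seed: int, subject_index: int, repeat: int
                ) -> np.random.Generator:
    """All protocol randomness flows from the master seed through
    SeedSequence spawn keys (subject_index, repeat)."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed,
                               spawn_key=(subject_index, repeat))
    )


def split_protocol(
    subject_ids: np.ndarray, config: ProtocolConfig
) -> list[dict]:
    """Per-(subject, repeat) train/test index sets.

    Returns dicts with keys ``subject``, ``repeat``, ``train``, ``test``
    (integer index arrays into the dataset rows).
    """
    subject_ids = np.asarray(subject_ids)
    subjects = list(dict.fromkeys(subject_ids))  # stable order
    splits = []
    for si, subj in enumerate(subjects):
        own = np.flatnonzero(subject_ids == subj)
        others = np.flatnonzero(subject_ids != subj)
        n_test = int(round(config.test_fraction * len(own)))
        if n_test < 1:
            raise ValueError(
                f"subject {subj} has too few epochs ({len(own)}) for a "
                f"{config.test_fraction:.0%} test sample"
            )
        for rep in range(config.repeats):
            rng = _repeat_rng(config.seed, si, rep)
            perm = rng.permutation(own)
            test = np.sort(perm[:n_test])
            if config.mode == "generalized":
                train = others
            else:
                train = np.sort(perm[n_test:])
            splits.append(
                {"subject": subj, "repeat": rep, "train": train,
                 "test": test}
            )
    return splits


# ---------------------------------------------------------------------------
# metrics

def compute_metrics(predictions: np.ndarray, truths: np.ndarray) -> dict:
    """MAE (%) and RMSE (cm/s) with the SDs of the per-epoch quantities.

    MAE% is the mean relative absolute error ``|y_hat - y| / y * 100``;
    its SD is the SD of the per-epoch relative errors.  RMSE is in the
    units of y (cm/s); its SD is the SD of the per-epoch absolute errors.
    """
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must align")
    if np.any(truths <= 0):
        raise ValueError("truth speeds must be positive")
    abs_err = np.abs(predictions - truths)
    rel_pct = abs_err / truths * 100.0
    return {
        "mae_pct": float(np.mean(rel_pct)),
        "mae_sd_pct": float(np.std(rel_pct, ddof=1)) if len(rel_pct) > 1
        else 0.0,
        "rmse": float(np.sqrt(np.mean(abs_err**2))),
        "rmse_sd": float(np.std(abs_err, ddof=1)) if len(abs_err) > 1
        else 0.0,
        "n": int(len(truths)),
    }


def bland_altman(predictions: np.ndarray, truths: np.ndarray) -> dict:
    """Bias and 95 % limits of agreement of ``d = y_hat - y``."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if len(predictions) < 3:
        raise ValueError("need at least 3 pairs")
    d = predictions - truths
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lower, upper = bias - 1.96 * sd, bias + 1.96 * sd
    outliers = np.flatnonzero((d < lower) | (d > upper))
    return {
        "bias": bias,
        "sd": sd,
        "lower_limit": lower,
        "upper_limit": upper,
        "outliers": outliers.tolist(),
    }


def regime_breakdown(
    predictions: np.ndarray,
    truths: np.ndarray,
    regimes: dict[str, tuple[float, float]] | None = None,
) -> dict[str, dict]:
    """Metrics per true-speed regime bucket; empty buckets are absent.

    Buckets are lower-inclusive half-open intervals; the fastest bucket
    is closed at its upper edge.
    """
    regimes = regimes or REGIMES
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    upper_edge = max(hi for _, hi in regimes.values())
    out = {}
    for name, (lo, hi) in regimes.items():
        mask = (truths >= lo) & (truths < hi)
        if hi == upper_edge:
            mask |= truths == hi
        if np.any(mask):
            out[name] = compute_metrics(predictions[mask], truths[mask])
    return out


def compare_methods(*error_groups: np.ndarray) -> dict:
    """One-way ANOVA across methods' per-subject error summaries."""
    if len(error_groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in error_groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
    f_stat, p = stats.f_oneway(*error_groups)
    return {"f": float(f_stat), "p": float(p)}


def pearson_correlation(predictions: np.ndarray, truths: np.ndarray
                        ) -> dict:
    """Pearson r (with p) and the least-squares line of y_hat on y."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if len(predictions) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(predictions) < 1e-12 or np.std(truths) < 1e-12:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(truths, predictions)
    fit = stats.linregress(truths, predictions)
    return {
        "r": float(r),
        "p": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
    }


# ---------------------------------------------------------------------------
# protocol driver

@dataclass
class EvaluationReport:
    """Aggregated result of one protocol run."""

    config: ProtocolConfig
    mae_pct: float
    mae_sd_pct: float                  # SD of per-epoch relative errors
    mae_sd_pct_subjects: float         # SD of per-subject mean MAE%
    rmse: float
    rmse_sd: float
    rmse_sd_subjects: float
    per_subject: pd.DataFrame          # subject, mae_pct, rmse
    regimes: dict
    bland_altman: dict
    pearson: dict
    predictions: pd.DataFrame          # subject, repeat, truth, prediction

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "mae_pct": self.mae_pct,
            "mae_sd_pct": self.mae_sd_pct,
            "mae_sd_pct_subjects": self.mae_sd_pct_subjects,
            "rmse": self.rmse,
            "rmse_sd": self.rmse_sd,
            "rmse_sd_subjects": self.rmse_sd_subjects,
            "regimes": self.regimes,
            "bland_altman": {k: v for k, v in self.bland_altman.items()
                             if k != "outliers"},
            "pearson": self.pearson,
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=2)


def _fit_model(x_tr, y_tr, config: ProtocolConfig, seed: int):
    if config.model == "gpr":
        return GprModel.fit(
            x_tr, y_tr,
            n_restarts=config.gpr_restarts,
            max_iter=config.gpr_max_iter,
            noise_floor=config.gpr_noise_floor,
            mean_function=config.gpr_mean_function,
            seed=seed,
        )
    if config.model == "lasso":
        lam, _ = lasso_select_lambda(x_tr, y_tr, seed=seed)
        return LassoModel.fit(x_tr, y_tr, lam, tol=1e-6,
                              max_sweeps=30_000)
    raise ValueError(f"unknown model {config.model!r}")


def run_protocol(dataset: pd.DataFrame, config: ProtocolConfig
                 ) -> EvaluationReport:
    """Execute the full train/test protocol on an assembled dataset.

    In generalized mode the training set for a subject does not depend on
    the repeat (only the test sample is resampled), so each
    leave-subject-out model is fitted once and evaluated on every
    repeat's test sample.
    """
    x, y, subject_ids = design_matrix(
        dataset, include_fd=config.include_fd,
        include_anthro=config.include_anthro,
    )
    splits = split_protocol(subject_ids, config)

    # leave-subject-out integrity, asserted every run
    for sp in splits:
        assert not np.intersect1d(sp["train"], sp["test"]).size
        if config.mode == "generalized":
            assert not np.any(subject_ids[sp["train"]] == sp["subject"])

    def train_rows(idx: np.ndarray) -> np.ndarray:
        if config.train_speed_filter is None:
            return idx
        lo, hi = config.train_speed_filter
        keep = (y[idx] >= lo) & (y[idx] < hi)
        return idx[keep]

    pred_rows = []
    if config.mode == "generalized":
        subjects = list(dict.fromkeys(subject_ids))
        for si, subj in enumerate(subjects):
            own_splits = [s for s in splits if s["subject"] == subj]
            tr = train_rows(own_splits[0]["train"])
            model = _fit_model(x[tr], y[tr], config, seed=config.seed + si)
            own = np.flatnonzero(subject_ids == subj)
            pred_all = dict(zip(own, np.atleast_1d(model.predict(x[own]))))
            for sp in own_splits:
                for i in sp["test"]:
                    pred_rows.append(
                        (subj, sp["repeat"], y[i], pred_all[i])
                    )
    else:
        for sp in splits:
            tr = train_rows(sp["train"])
            si = list(dict.fromkeys(subject_ids)).index(sp["subject"])
            model = _fit_model(
                x[tr], y[tr], config,
                seed=config.seed + 1000 * si + sp["repeat"],
            )
            preds = np.atleast_1d(model.predict(x[sp["test"]]))
            for i, p in zip(sp["test"], preds):
                pred_rows.append((sp["subject"], sp["repeat"], y[i], p))

    preds = pd.DataFrame(
        pred_rows, columns=["subject", "repeat", "truth", "prediction"]
    )

    # average across repeats within subject, then across subjects
    subj_stats = []
    for subj, grp in preds.groupby("subject", sort=False):
        per_rep = [
            compute_metrics(g["prediction"].to_numpy(),
                            g["truth"].to_numpy())
            for _, g in grp.groupby("repeat")
        ]
        subj_stats.append(
            {
                "subject": subj,
                "mae_pct": np.mean([m["mae_pct"] for m in per_rep]),
                "rmse": np.mean([m["rmse"] for m in per_rep]),
            }
        )
    per_subject = pd.DataFrame(subj_stats)

    pooled = compute_metrics(
        preds["prediction"].to_numpy(), preds["truth"].to_numpy()
    )
    return EvaluationReport(
        config=config,
        mae_pct=float(per_subject["mae_pct"].mean()),
        mae_sd_pct=pooled["mae_sd_pct"],
        mae_sd_pct_subjects=float(per_subject["mae_pct"].std(ddof=1))
        if len(per_subject) > 1 else 0.0,
        rmse=float(per_subject["rmse"].mean()),
        rmse_sd=pooled["rmse_sd"],
        rmse_sd_subjects=float(per_subject["rmse"].std(ddof=1))
        if len(per_subject) > 1 else 0.0,
        per_subject=per_subject,
        regimes=regime_breakdown(
            preds["prediction"].to_numpy(), preds["truth"].to_numpy()
        ),
        bland_altman=bland_altman(
            preds["prediction"].to_numpy(), preds["truth"].to_numpy()
        ),
        pearson=pearson_correlation(
            preds["prediction"].to_numpy(), preds["truth"].to_numpy()
        ),
        predictions=preds,
    )
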