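"""Walking-speed regressors: Gaussian-process regression with a squared-
exponential ARD covariance, and ℓ1-regularized least squares (Lasso).

GPR models ``y_i = f(x_i) + eps_i`` with ``eps ~ N(0, sigma_n^2)`` and

    k(x, x') = sigma_f^2 * exp(-0.5 * sum_d (x_d - x'_d)^2 / l_d^2)

The per-dimension length scales implement automatic relevance
determination: a large ``l_d`` switches feature ``d`` off.  The predictive
mean and variance at ``x*`` are

    mu(x*)     = k*^T (K + sigma_n^2 I)^{-1} y
    sigma^2(x*) = k(x*, x*) - k*^T (K + sigma_n^2 I)^{-1} k*

Hyperparameters maximize the log marginal likelihood (gradient ascent in
log space, seeded random restarts).  Features and targets are z-scored
internally; the standardization record is stored with the model.

The Lasso minimizes ``0.5 * sum_i (y_i - b0 - x_i^T b)^2 + lam * sum_j |b_j|``
(intercept unpenalized) by cyclic coordinate descent with exact
soft-thresholding, so inactive coefficients are exactly zero.  ``lam`` is
chosen by 10-fold cross-validation over a log-spaced grid descending from
``lam_max`` (the smallest penalty with an all-zero solution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numba
import numpy as np
from scipy import linalg, optimize


# ---------------------------------------------------------------------------
# standardization helpers

@dataclass
class Standardizer:
    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        x = np.asarray(x, dtype=float)
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        return cls(mean=mean, scale=scale)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.scale


# ---------------------------------------------------------------------------
# SE-ARD kernel

def se_ard_kernel(
    x_i: np.ndarray,
    x_j: np.ndarray,
    signal_variance: float,
    length_scales: np.ndarray,
) -> np.ndarray:
    """Squared-exponential ARD covariance between two points or row sets.

    ``k = sigma_f^2 * exp(-0.5 * sum_d (x_i,d - x_j,d)^2 / l_d^2)``.
    Scalars are returned for 1-D inputs, matrices for 2-D inputs.
    """
    if signal_variance <= 0:
        raise ValueError("signal_variance must be positive")
    ls = np.atleast_1d(np.asarray(length_scales, dtype=float))
    if np.any(ls <= 0):
        raise ValueError("length scales must be positive")
    a = np.atleast_2d(np.asarray(x_i, dtype=float)) / ls
    b = np.atleast_2d(np.asarray(x_j, dtype=float)) / ls
    sq = (
        np.sum(a**2, axis=1)[:, None]
        + np.sum(b**2, axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    k = signal_variance * np.exp(-0.5 * np.maximum(sq, 0.0))
    if np.ndim(x_i) == 1 and np.ndim(x_j) == 1:
        return float(k[0, 0])
    return k


def _cholesky_with_jitter(k: np.ndarray, signal_variance: float
                          ) -> tuple[np.ndarray, float]:
    """Cholesky of a kernel matrix, escalating jitter 1e-10..1e-6 * sigma_f^2."""
    jitter = 1e-10 * signal_variance
    for _ in range(5):
        try:
            return linalg.cholesky(
                k + jitter * np.eye(len(k)), lower=True
            ), jitter
        except linalg.LinAlgError:
            jitter *= 10.0
    raise linalg.LinAlgError(
        f"covariance not positive definite even with jitter {jitter:.1e}"
    )


def _ridge_gcv(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Ridge coefficients with the penalty chosen by generalized
    cross-validation (SVD closed form)."""
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    uty = u.T @ ys
    n = len(ys)
    best_alpha, best_gcv = 1.0, np.inf
    for alpha in np.geomspace(1e-3, 1e3, 25):
        shrink = s**2 / (s**2 + alpha)
        resid_ss = float(np.sum(((1.0 - shrink) * uty) ** 2)) + float(
            ys @ ys - uty @ uty
        )
        dof = n - float(np.sum(shrink))
        gcv = resid_ss / max(dof, 1e-9) ** 2
        if gcv < best_gcv:
            best_gcv, best_alpha = gcv, alpha
    shrink = s / (s**2 + best_alpha)
    return vt.T @ (shrink * uty)


@dataclass
class GprModel:
    """Fitted Gaussian-process regressor.

    The default prior mean is zero on z-scored targets (the plain
    posterior equations).  ``mean_function="linear"`` (ridge,
    GCV-penalized) or ``"lasso"`` (ℓ1, CV-penalized) fits a linear trend
    first and models its residuals with the zero-mean GP — the standard
    explicit-basis-function construction, which keeps the model at least
    as expressive as a regularized linear fit when queries fall outside
    the training distribution.
    """

    x_train: np.ndarray          # standardized training inputs
    signal_variance: float
    length_scales: np.ndarray
    noise_variance: float
    alpha: np.ndarray            # cached (K + sigma_n^2 I)^{-1} resid
    chol: np.ndarray             # cached lower Cholesky factor
    x_std: Standardizer
    y_mean: float
    y_scale: float
    mean_coef: np.ndarray | None = None  # linear mean on standardized x
    mean_intercept: float = 0.0
    log_marginal_likelihood: float = float("nan")

    # --- fitting ------------------------------------------------------
    @classmethod
    def fit(
        cls,
        x: np.ndarray,
        y: np.ndarray,
        n_restarts: int = 5,
        seed: int = 0,
        max_iter: int = 100,
        optimize_hyperparameters: bool = True,
        init_hyperparameters: tuple | None = None,
        noise_floor: float = 1e-3,
        mean_function: str = "none",
    ) -> "GprModel":
        """Fit hyperparameters by maximizing the log marginal likelihood.

        ``init_hyperparameters`` is an optional
        ``(signal_variance, length_scales, noise_variance)`` triple; with
        ``optimize_hyperparameters=False`` it is used as-is.
        ``noise_floor`` lower-bounds sigma_n during optimization (in
        standardized-target units): targets carry measurement error, and
        letting the marginal likelihood drive sigma_n to zero makes the
        model interpolate its training cohort.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 2 or len(x) != len(y):
            raise ValueError("x must be (N, D) aligned with y")
        if len(y) < 2:
            raise ValueError("need at least 2 training samples")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite training data")

        x_std = Standardizer.fit(x)
        xs = x_std.transform(x)
        y_mean = float(np.mean(y))
        y_scale = float(np.std(y))
        if y_scale < 1e-12:
            y_scale = 1.0
        ys = (y - y_mean) / y_scale
        n, d = xs.shape

        mean_intercept = 0.0
        if mean_function == "linear":
            mean_coef = _ridge_gcv(xs, ys)
            ys = ys - xs @ mean_coef
        elif mean_function == "lasso":
            # sparse linear trend chosen by the same CV procedure as the
            # standalone Lasso; the GP then models its residuals
            lam, _ = lasso_select_lambda(xs, ys, seed=seed)
            trend = LassoModel.fit(xs, ys, lam, standardize=False,
                                   tol=1e-6, max_sweeps=30_000,
                                   strict=False)
            mean_coef = trend.coefficients
            mean_intercept = trend.intercept
            ys = ys - (xs @ mean_coef + mean_intercept)
        elif mean_function == "none":
            mean_coef = None
        else:
            raise ValueError(f"unknown mean_function {mean_function!r}")

        if init_hyperparameters is not None:
            sf2, ls, sn2 = init_hyperparameters
            theta0 = np.concatenate(
                [[0.5 * np.log(sf2)], np.log(np.atleast_1d(ls)),
                 [0.5 * np.log(sn2)]]
            )
        else:
            # median-distance heuristic: in D standardized dimensions
            # typical squared distances are ~2D, so per-dimension length
            # scales of sqrt(D) give an O(1) initial kernel; starting at
            # l=1 makes the initial kernel effectively diagonal and
            # strands the optimizer in a memorization basin
            theta0 = np.concatenate(
                [[0.0], np.full(d, 0.5 * np.log(max(d, 2))),
                 [np.log(0.3)]]
            )

        if not optimize_hyperparameters:
            best_theta = theta0
        else:
            sqd = _sq_diff_stack(xs)
            rng = np.random.default_rng(seed)
            bounds = (
                [(-5.0, 5.0)]            # log sigma_f
                + [(-5.0, 5.0)] * d      # log length scales
                + [(max(np.log(noise_floor), -7.0), 2.0)]  # log sigma_n
            )
            best_theta, best_nll = None, np.inf
            for r in range(max(1, n_restarts)):
                start = theta0 if r == 0 else theta0 + rng.normal(
                    0.0, 1.0, size=len(theta0)
                )
                start = np.clip(start, [b[0] for b in bounds],
                                [b[1] for b in bounds])
                res = optimize.minimize(
                    _neg_log_marginal_likelihood,
                    start,
                    args=(xs, ys, sqd),
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": max_iter},
                )
                if res.fun < best_nll:
                    best_nll, best_theta = res.fun, res.x

        sf2 = float(np.exp(2.0 * best_theta[0]))
        ls = np.exp(best_theta[1:-1])
        sn2 = float(np.exp(2.0 * best_theta[-1]))

        k = se_ard_kernel(xs, xs, sf2, ls) + sn2 * np.eye(n)
        chol, _ = _cholesky_with_jitter(k, sf2)
        alpha = linalg.cho_solve((chol, True), ys)
        lml = (
            -0.5 * float(ys @ alpha)
            - float(np.sum(np.log(np.diag(chol))))
            - 0.5 * n * np.log(2.0 * np.pi)
        )
        return cls(
            x_train=xs,
            signal_variance=sf2,
            length_scales=ls,
            noise_variance=sn2,
            alpha=alpha,
            chol=chol,
            x_std=x_std,
            y_mean=y_mean,
            y_scale=y_scale,
            mean_coef=mean_coef,
            mean_intercept=mean_intercept,
            log_marginal_likelihood=lml,
        )

    # --- prediction ---------------------------------------------------
    def predict(self, x_new: np.ndarray, return_variance: bool = False):
        """Predictive mean (and latent variance) at new inputs.

        The variance is clipped below at zero and, by construction,
        never exceeds ``k(x*, x*) = signal_variance`` (in standardized-y
        units; returned in original units of y²).
        """
        x_new = np.asarray(x_new, dtype=float)
        single = x_new.ndim == 1
        xq = self.x_std.transform(np.atleast_2d(x_new))
        if xq.shape[1] != self.x_train.shape[1]:
            raise ValueError("feature dimension mismatch")
        k_star = se_ard_kernel(
            xq, self.x_train, self.signal_variance, self.length_scales
        )
        mean_std = k_star @ self.alpha
        if self.mean_coef is not None:
            mean_std = mean_std + xq @ self.mean_coef + self.mean_intercept
        mean = mean_std * self.y_scale + self.y_mean
        if not return_variance:
            return mean[0] if single else mean
        v = linalg.solve_triangular(self.chol, k_star.T, lower=True)
        var_std = self.signal_variance - np.sum(v**2, axis=0)
        var = np.clip(var_std, 0.0, None) * self.y_scale**2
        if single:
            return mean[0], var[0]
        return mean, var

    # --- serialization ------------------------------------------------
    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            format_version=1,
            x_train=self.x_train,
            signal_variance=self.signal_variance,
            length_scales=self.length_scales,
            noise_variance=self.noise_variance,
            alpha=self.alpha,
            chol=self.chol,
            x_mean=self.x_std.mean,
            x_scale=self.x_std.scale,
            y_mean=self.y_mean,
            y_scale=self.y_scale,
            mean_coef=(self.mean_coef if self.mean_coef is not None
                       else np.empty(0)),
            mean_intercept=self.mean_intercept,
            log_marginal_likelihood=self.log_marginal_likelihood,
        )

    @classmethod
    def load(cls, path: str | Path) -> "GprModel":
        with np.load(path) as f:
            if int(f["format_version"]) != 1:
                raise ValueError("unsupported model format version")
            return cls(
                x_train=f["x_train"],
                signal_variance=float(f["signal_variance"]),
                length_scales=f["length_scales"],
                noise_variance=float(f["noise_variance"]),
                alpha=f["alpha"],
                chol=f["chol"],
                x_std=Standardizer(mean=f["x_mean"], scale=f["x_scale"]),
                y_mean=float(f["y_mean"]),
                y_scale=float(f["y_scale"]),
                mean_coef=(f["mean_coef"] if len(f["mean_coef"])
                           else None),
                mean_intercept=float(f["mean_intercept"]),
                log_marginal_likelihood=float(
                    f["log_marginal_likelihood"]
                ),
            )


def _neg_log_marginal_likelihood(theta: np.ndarray, xs: np.ndarray,
                                 ys: np.ndarray,
                                 sqd: np.ndarray | None = None):
    """Negative LML and its gradient w.r.t. log hyperparameters.

    ``theta = [log sigma_f, log l_1..D, log sigma_n]``.  ``sqd`` is the
    optional precomputed (D, N, N) stack of per-dimension squared
    differences (it does not depend on the hyperparameters).
    """
    n, d = xs.shape
    sf2 = np.exp(2.0 * theta[0])
    ls = np.exp(theta[1:-1])
    sn2 = np.exp(2.0 * theta[-1])

    if sqd is None:
        sqd = _sq_diff_stack(xs)
    sq = np.tensordot(1.0 / ls**2, sqd, axes=1)
    np.maximum(sq, 0.0, out=sq)
    k_f = sf2 * np.exp(-0.5 * sq)
    k = k_f + sn2 * np.eye(n)
    try:
        chol, _ = _cholesky_with_jitter(k, sf2)
    except linalg.LinAlgError:
        return 1e25, np.zeros_like(theta)
    alpha = linalg.cho_solve((chol, True), ys)
    nll = (
        0.5 * float(ys @ alpha)
        + float(np.sum(np.log(np.diag(chol))))
        + 0.5 * n * np.log(2.0 * np.pi)
    )

    k_inv = linalg.cho_solve((chol, True), np.eye(n))
    w = np.outer(alpha, alpha) - k_inv  # dLML/dK = 0.5 * W

    grad = np.empty_like(theta)
    wk = w * k_f
    grad[0] = -float(np.sum(wk))                    # d/d log sigma_f
    grad[1:-1] = -0.5 * np.tensordot(sqd, wk, axes=([1, 2], [0, 1])) / ls**2
    grad[-1] = -float(np.trace(w)) * sn2            # d/d log sigma_n
    return nll, grad


def _sq_diff_stack(xs: np.ndarray) -> np.ndarray:
    """(D, N, N) per-dimension squared differences."""
    diffs = xs.T[:, :, None] - xs.T[:, None, :]
    return diffs**2


# ---------------------------------------------------------------------------
# Lasso

@dataclass
class LassoModel:
    """ℓ1-penalized linear model with unpenalized intercept."""

    intercept: float
    coefficients: np.ndarray      # in original feature units
    penalty: float
    x_std: Standardizer | None
    n_sweeps: int = 0
    objective_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    @classmethod
    def fit(
        cls,
        x: np.ndarray,
        y: np.ndarray,
        lam: float,
        standardize: bool = True,
        tol: float = 1e-8,
        obj_rtol: float = 0.0,
        max_sweeps: int = 10_000,
        coef_init: np.ndarray | None = None,
        strict: bool = True,
    ) -> "LassoModel":
        """Cyclic coordinate descent on the penalized least-squares
        objective.

        Converged when the largest coefficient change in a sweep falls
        below ``tol`` (relative to the coefficient scale) or, if
        ``obj_rtol`` > 0, when the objective decrease per sweep stalls
        below it (relative) — on near-collinear designs coefficients can
        keep trading against each other long after the fit itself has
        stopped improving.  With ``strict=False`` hitting the sweep cap
        returns the current iterate instead of raising (used for
        best-effort fits inside cross-validation)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        if x.ndim != 2 or len(x) != len(y) or len(y) < 2:
            raise ValueError("x must be (N>=2, D) aligned with y")
        n, d = x.shape

        x_std = Standardizer.fit(x) if standardize else None
        xs = x_std.transform(x) if standardize else x
        y_off = float(np.mean(y))
        yc = y - y_off

        # Gram formulation: each coordinate update is O(D), not O(N)
        gram = xs.T @ xs
        c = xs.T @ yc
        yty = float(yc @ yc)
        col_sq = np.diag(gram).copy()
        beta = (np.zeros(d) if coef_init is None
                else np.asarray(coef_init, dtype=float).copy())

        beta, objective, n_sweeps, max_delta = _cd_sweeps(
            np.ascontiguousarray(gram), c, yty, float(lam), float(tol),
            float(obj_rtol), int(max_sweeps), beta,
        )
        objective = list(objective[:n_sweeps])
        if n_sweeps == max_sweeps and strict:
            scale = max(1.0, float(np.max(np.abs(beta))) if d else 1.0)
            if max_delta >= tol * scale:
                raise RuntimeError(
                    f"coordinate descent did not converge in {max_sweeps} "
                    f"sweeps (last sweep max change {max_delta:.2e})"
                )
        sweep = n_sweeps - 1

        if standardize:
            coef = beta / x_std.scale
            intercept = y_off - float(coef @ x_std.mean)
        else:
            coef = beta
            intercept = y_off
        model = cls(
            intercept=intercept,
            coefficients=coef,
            penalty=float(lam),
            x_std=x_std,
            n_sweeps=sweep + 1,
            objective_path=np.asarray(objective),
        )
        model._beta_internal = beta
        return model

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.asarray(x_new, dtype=float)
        single = x_new.ndim == 1
        out = np.atleast_2d(x_new) @ self.coefficients + self.intercept
        return float(out[0]) if single else out

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            format_version=1,
            intercept=self.intercept,
            coefficients=self.coefficients,
            penalty=self.penalty,
            x_mean=(self.x_std.mean if self.x_std is not None
                    else np.empty(0)),
            x_scale=(self.x_std.scale if self.x_std is not None
                     else np.empty(0)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LassoModel":
        with np.load(path) as f:
            if int(f["format_version"]) != 1:
                raise ValueError("unsupported model format version")
            std = None
            if len(f["x_mean"]):
                std = Standardizer(mean=f["x_mean"], scale=f["x_scale"])
            return cls(
                intercept=float(f["intercept"]),
                coefficients=f["coefficients"],
                penalty=float(f["penalty"]),
                x_std=std,
            )


def _soft_threshold(z: float, lam: float) -> float:
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


@numba.njit(cache=True)
def _cd_sweeps(gram, c, yty, lam, tol, obj_rtol, max_sweeps, beta):
    """Cyclic coordinate-descent sweeps on the Gram formulation.

    Returns (beta, per-sweep objectives, sweeps run, last max change).
    """
    d = gram.shape[0]
    q = gram @ beta
    objective = np.empty(max_sweeps)
    max_delta = 0.0
    n_sweeps = 0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(d):
            gjj = gram[j, j]
            if gjj < 1e-300:
                continue
            old = beta[j]
            rho = c[j] - q[j] + gjj * old
            if rho > lam:
                new = (rho - lam) / gjj
            elif rho < -lam:
                new = (rho + lam) / gjj
            else:
                new = 0.0
            if new != old:
                delta = new - old
                for i in range(d):
                    q[i] += gram[i, j] * delta
                beta[j] = new
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        obj = 0.5 * yty + lam * np.sum(np.abs(beta))
        for i in range(d):
            obj += beta[i] * (0.5 * q[i] - c[i])
        objective[sweep] = obj
        n_sweeps = sweep + 1
        scale = np.max(np.abs(beta)) if d > 0 else 0.0
        if scale < 1.0:
            scale = 1.0
        if max_delta < tol * scale:
            break
        if obj_rtol > 0.0 and sweep >= 1:
            ref = objective[sweep]
            if ref < 1.0:
                ref = 1.0
            if objective[sweep - 1] - objective[sweep] < obj_rtol * ref:
                break
    return beta, objective, n_sweeps, max_delta


def lasso_lambda_max(x: np.ndarray, y: np.ndarray,
                     standardize: bool = True) -> float:
    """Smallest penalty for which the Lasso solution is identically zero:
    ``max_j |x_j^T (y - mean(y))|`` on (optionally) standardized columns."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xs = Standardizer.fit(x).transform(x) if standardize else x
    return float(np.max(np.abs(xs.T @ (y - y.mean()))))


def lasso_path_grid(x: np.ndarray, y: np.ndarray, n_values: int = 50,
                    ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced penalty grid descending from ``lam_max``."""
    lam_max = lasso_lambda_max(x, y)
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, ratio * lam_max, n_values)


def lasso_select_lambda(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
    tol: float = 1e-5,
) -> tuple[float, np.ndarray]:
    """Pick the penalty minimizing mean 10-fold cross-validated squared
    error; ties resolve to the largest (most regularized) penalty.

    The per-fold fits run at a relaxed tolerance: near-collinear designs
    (neighboring FFT bins) make coordinate descent zigzag at the small
    end of the penalty path, and CV only needs the fold MSE.

    Returns ``(lam_star, cv_mse_per_grid_value)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError("need at least as many samples as folds")
    if grid is None:
        grid = lasso_path_grid(x, y)
    grid = np.asarray(grid, dtype=float)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = np.array_split(perm, folds)
    if any(len(f) == 0 for f in fold_ids):
        raise ValueError("degenerate folds: a fold is empty")

    cv_mse = np.zeros(len(grid))
    for test_idx in fold_ids:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        x_tr, y_tr = x[mask], y[mask]
        x_te, y_te = x[test_idx], y[test_idx]
        coef = None
        for gi, lam in enumerate(grid):  # warm start down the path
            model = LassoModel.fit(
                x_tr, y_tr, lam, coef_init=coef, tol=tol,
                obj_rtol=1e-10, max_sweeps=2000, strict=False,
            )
            coef = model._beta_internal
            pred = model.predict(x_te)
            cv_mse[gi] += float(np.sum((pred - y_te) ** 2))
    cv_mse /= n
    best = int(np.argmin(cv_mse))  # grid descends, argmin takes largest lam
    return float(grid[best]), cv_mse
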