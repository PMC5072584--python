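"""GPR and Lasso: kernel algebra, oracle equivalence, KKT conditions."""

import numpy as np
import pytest
from scipy import linalg

from wristspeed.regression import (
    GprModel,
    LassoModel,
    Standardizer,
    lasso_lambda_max,
    lasso_select_lambda,
    se_ard_kernel,
)


def dense_gp_oracle(x_train, y_train, x_query, sf2, ls, sn2):
    """Brute-force dense-matrix evaluation of the GP posterior."""
    k = se_ard_kernel(x_train, x_train, sf2, ls) + sn2 * np.eye(len(x_train))
    k_inv = np.linalg.inv(k)
    k_star = se_ard_kernel(x_query, x_train, sf2, ls)
    mean = k_star @ k_inv @ y_train
    var = sf2 - np.einsum("ij,jk,ik->i", k_star, k_inv, k_star)
    return mean, var


class TestKernel:
    def test_same_point_gives_signal_variance(self):
        x = np.array([1.0, 2.0, 3.0])
        assert np.isclose(se_ard_kernel(x, x, 2.5, np.ones(3)), 2.5)

    def test_unit_lengthscale_example(self):
        assert np.isclose(
            se_ard_kernel(np.array([0.0]), np.array([np.sqrt(2.0)]), 1.0,
                          np.array([1.0])),
            np.exp(-1.0),
        )

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b = rng.normal(size=(2, 4))
            ls = np.abs(rng.normal(size=4)) + 0.1
            assert se_ard_kernel(a, b, 1.3, ls) == se_ard_kernel(
                b, a, 1.3, ls
            )

    def test_rejects_nonpositive_hyperparameters(self):
        x = np.zeros(2)
        with pytest.raises(ValueError):
            se_ard_kernel(x, x, -1.0, np.ones(2))
        with pytest.raises(ValueError):
            se_ard_kernel(x, x, 1.0, np.array([1.0, 0.0]))


class TestGpr:
    def test_zero_targets_zero_predictions(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 3))
        model = GprModel.fit(x, np.zeros(20), n_restarts=1, max_iter=20)
        pred = model.predict(rng.normal(size=(5, 3)))
        np.testing.assert_allclose(pred, 0.0, atol=1e-9)

    def test_interpolates_training_point_at_tiny_noise(self):
        x = np.array([[0.0], [5.0]])
        y = np.array([1.0, 3.0])
        model = GprModel.fit(
            x, y, optimize_hyperparameters=False,
            init_hyperparameters=(1.0, np.array([1.0]), 1e-10),
        )
        mu, var = model.predict(np.array([0.0]), return_variance=True)
        assert abs(mu - 1.0) < 1e-5
        assert var < 1e-6

    def test_far_query_reverts_to_prior(self):
        x = np.array([[0.0], [1.0], [2.0]])
        y = np.array([1.0, 2.0, 3.0])
        model = GprModel.fit(
            x, y, optimize_hyperparameters=False,
            init_hyperparameters=(1.0, np.array([0.5]), 0.01),
        )
        mu, var = model.predict(np.array([1000.0]), return_variance=True)
        # prior mean is the training mean; variance approaches sigma_f^2
        assert abs(mu - y.mean()) < 1e-6
        assert abs(var - model.signal_variance * model.y_scale**2) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_oracle(self, seed):
        """Posterior mean and variance equal an independent dense-matrix
        evaluation to 1e-10 on random toy sets."""
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 50)
        d = rng.integers(1, 4)
        x = rng.normal(size=(n, d))
        y = rng.normal(size=n)
        sf2, sn2 = 1.7, 0.09
        ls = np.abs(rng.normal(1.0, 0.3, size=d)) + 0.2
        model = GprModel.fit(
            x, y, optimize_hyperparameters=False,
            init_hyperparameters=(sf2, ls, sn2),
        )
        xq = rng.normal(size=(7, d))
        mu, var = model.predict(xq, return_variance=True)
        # oracle works on the model's standardized internals
        xs = model.x_std.transform(x)
        xqs = model.x_std.transform(xq)
        ys = (y - model.y_mean) / model.y_scale
        mu_o, var_o = dense_gp_oracle(xs, ys, xqs, sf2, ls, sn2)
        np.testing.assert_allclose(
            mu, mu_o * model.y_scale + model.y_mean, atol=1e-10
        )
        np.testing.assert_allclose(
            var, np.clip(var_o, 0, None) * model.y_scale**2, atol=1e-10
        )

    def test_mean_linear_in_targets(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        hp = (1.0, np.ones(2), 0.1)
        m1 = GprModel.fit(x, y, optimize_hyperparameters=False,
                          init_hyperparameters=hp)
        m2 = GprModel.fit(x, 2 * y, optimize_hyperparameters=False,
                          init_hyperparameters=hp)
        xq = rng.normal(size=(6, 2))
        np.testing.assert_allclose(2 * m1.predict(xq), m2.predict(xq),
                                   atol=1e-8)

    def test_variance_bounded_by_alpha(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        model = GprModel.fit(x, y, n_restarts=1, max_iter=30)
        _, var = model.predict(rng.normal(size=(50, 2)) * 3,
                               return_variance=True)
        alpha = model.signal_variance * model.y_scale**2
        assert np.all(var >= 0.0)
        assert np.all(var <= alpha + 1e-9)

    def test_duplicated_training_set_same_mean(self):
        """Duplicating every training point must not move the posterior
        mean (the information is unchanged up to noise weighting)."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 2))
        y = x[:, 0] + 0.1 * rng.normal(size=12)
        hp = (1.0, np.ones(2), 0.2)
        m1 = GprModel.fit(x, y, optimize_hyperparameters=False,
                          init_hyperparameters=hp)
        m2 = GprModel.fit(
            np.vstack([x, x]), np.concatenate([y, y]),
            optimize_hyperparameters=False,
            # duplicated points halve the effective noise per site
            init_hyperparameters=(1.0, np.ones(2), 0.4),
        )
        grid = rng.normal(size=(20, 2))
        np.testing.assert_allclose(m1.predict(grid), m2.predict(grid),
                                   atol=1e-6)

    def test_ard_recovers_relevant_dimension(self):
        """Data from a known SE-ARD GP: the irrelevant dimension gets the
        longer fitted length scale (median over seeds)."""
        results = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            x = rng.uniform(-3, 3, size=(150, 2))
            k = se_ard_kernel(x, x, 1.0, np.array([1.0, 10.0]))
            y = rng.multivariate_normal(
                np.zeros(150), k + 0.01 * np.eye(150)
            )
            model = GprModel.fit(x, y, n_restarts=2, max_iter=60,
                                 seed=seed)
            results.append(model.length_scales[1] / model.length_scales[0])
        assert np.median(results) > 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        m1 = GprModel.fit(x, y, n_restarts=2, seed=9, max_iter=30)
        m2 = GprModel.fit(x, y, n_restarts=2, seed=9, max_iter=30)
        np.testing.assert_array_equal(m1.length_scales, m2.length_scales)

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        model = GprModel.fit(x, y, n_restarts=1, max_iter=20)
        path = tmp_path / "gpr.npz"
        model.save(path)
        loaded = GprModel.load(path)
        xq = rng.normal(size=(4, 2))
        np.testing.assert_allclose(model.predict(xq), loaded.predict(xq))


class TestLasso:
    def test_lambda_zero_matches_ols(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 2))
        y = x @ np.array([1.5, -2.0]) + 0.3 + 0.1 * rng.normal(size=10)
        model = LassoModel.fit(x, y, lam=0.0)
        xd = np.column_stack([np.ones(10), x])
        beta = np.linalg.solve(xd.T @ xd, xd.T @ y)
        assert abs(model.intercept - beta[0]) < 1e-8
        np.testing.assert_allclose(model.coefficients, beta[1:], atol=1e-8)

    def test_lambda_max_gives_null_model(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 4))
        y = rng.normal(size=30) + 5.0
        lam_max = lasso_lambda_max(x, y)
        model = LassoModel.fit(x, y, lam=lam_max * 1.0000001)
        assert np.all(model.coefficients == 0.0)
        assert np.isclose(model.intercept, y.mean())

    def test_orthonormal_design_soft_thresholds(self):
        """On an orthonormal design each coefficient is the
        soft-thresholded OLS coefficient."""
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.normal(size=(40, 5)))
        x = q  # columns orthonormal
        y = rng.normal(size=40)
        lam = 0.3
        model = LassoModel.fit(x, y, lam=lam, standardize=False)
        ols = x.T @ (y - y.mean())
        expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
        np.testing.assert_allclose(model.coefficients, expected, atol=1e-8)

    def test_kkt_conditions(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(50, 8))
        y = x[:, 0] - 2 * x[:, 3] + 0.5 * rng.normal(size=50)
        lam = 5.0
        model = LassoModel.fit(x, y, lam=lam)
        beta = model._beta_internal
        xs = model.x_std.transform(x)
        r = (y - y.mean()) - xs @ beta
        grad = xs.T @ r
        tol = 1e-6
        for j in range(8):
            if beta[j] == 0.0:
                assert abs(grad[j]) <= lam + tol
            else:
                assert abs(grad[j] - np.sign(beta[j]) * lam) <= tol

    def test_objective_nonincreasing(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(60, 10))
        y = rng.normal(size=60)
        model = LassoModel.fit(x, y, lam=2.0)
        obj = model.objective_path
        assert np.all(np.diff(obj) <= 1e-12)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            LassoModel.fit(np.zeros((5, 2)), np.zeros(5), lam=-1.0)

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        model = LassoModel.fit(x, y, lam=0.5)
        model.save(tmp_path / "lasso.npz")
        loaded = LassoModel.load(tmp_path / "lasso.npz")
        np.testing.assert_allclose(model.predict(x), loaded.predict(x))


class TestLassoCv:
    def test_noiseless_linear_data_picks_small_lambda(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 3))
        y = x @ np.array([2.0, -1.0, 0.5])
        lam, _ = lasso_select_lambda(x, y, seed=0)
        grid = np.geomspace(1, 1e-4, 50)
        assert lam <= lasso_lambda_max(x, y) * 1e-2

    def test_pure_noise_picks_large_lambda(self):
        picks = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=(60, 5))
            y = rng.normal(size=60)
            lam, _ = lasso_select_lambda(x, y, seed=seed)
            picks.append(lam / lasso_lambda_max(x, y))
        # majority of seeds keep lambda near the top of the grid
        assert np.median(picks) > 0.1

    def test_cv_curve_matches_refit_oracle(self):
        """The CV curve equals a brute-force re-fit-per-fold computation."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 3))
        y = x[:, 0] + 0.2 * rng.normal(size=30)
        grid = np.geomspace(lasso_lambda_max(x, y), 1e-3, 8)
        lam, curve = lasso_select_lambda(x, y, grid=grid, folds=5, seed=3,
                                         tol=1e-8)

        perm = np.random.default_rng(3).permutation(30)
        folds = np.array_split(perm, 5)
        oracle = np.zeros(len(grid))
        for te in folds:
            mask = np.ones(30, dtype=bool)
            mask[te] = False
            for gi, g in enumerate(grid):
                m = LassoModel.fit(x[mask], y[mask], lam=g)
                oracle[gi] += np.sum((m.predict(x[te]) - y[te]) ** 2)
        oracle /= 30
        # the CV path itself runs at a relaxed convergence tolerance
        np.testing.assert_allclose(curve, oracle, rtol=1e-4)

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            lasso_select_lambda(np.zeros((5, 2)), np.zeros(5), folds=10)


def test_gpr_semiparametric_roundtrip(tmp_path):
    """A model with a sparse linear mean survives save/load including
    the trend coefficients."""
    rng = np.random.default_rng(6)
    x = rng.normal(size=(40, 3))
    y = 2 * x[:, 0] + 0.1 * rng.normal(size=40)
    model = GprModel.fit(x, y, n_restarts=1, max_iter=50,
                         mean_function="lasso")
    assert model.mean_coef is not None
    model.save(tmp_path / "m.npz")
    loaded = GprModel.load(tmp_path / "m.npz")
    q = rng.normal(size=(6, 3))
    np.testing.assert_allclose(model.predict(q), loaded.predict(q))
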