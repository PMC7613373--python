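"""Gaussian process regression against dense linear-algebra oracles."""

import numpy as np
import pytest

from cncmap import gpr


@pytest.fixture()
def theta():
    return gpr.Hyperparameters(1.3, np.array([0.8, 1.1, 0.9]), 0.2)


def _dense_oracle(X, y, Xs, theta, include_noise=False):
    """Predictive mean/variance by explicit matrix inversion."""
    A = gpr.kernel_matrix(X, X, theta) + theta.sigma_n**2 * np.eye(len(X))
    Ainv = np.linalg.inv(A)
    Ks = gpr.kernel_matrix(Xs, X, theta)
    yc = y - y.mean()
    mean = Ks @ Ainv @ yc + y.mean()
    kss = theta.nu + (theta.sigma_n**2 if include_noise else 0.0)
    var = kss - np.sum(Ks @ Ainv * Ks, axis=1)
    return mean, var


def _model_from_theta(X, y, theta, mode="ard"):
    A = gpr.kernel_matrix(X, X, theta, add_noise=True)
    L = np.linalg.cholesky(A)
    yc = y - y.mean()
    return gpr.GPRModel(X, y, float(y.mean()), theta, np.linalg.solve(A, yc), L, mode, 0.0)


class TestKernel:
    def test_self_covariance_with_and_without_noise(self, theta):
        x = np.array([0.3, -1.2, 2.0])
        assert gpr.kernel(x, x, theta, same_index=True) == pytest.approx(
            theta.nu + theta.sigma_n**2
        )
        assert gpr.kernel(x, x, theta, same_index=False) == pytest.approx(theta.nu)

    def test_decay_to_zero(self, theta):
        x = np.zeros(3)
        far = np.full(3, 100.0)
        assert gpr.kernel(x, far, theta) < 1e-12

    def test_hand_computed_value(self):
        th = gpr.Hyperparameters(2.0, np.array([1.0, 2.0]), 0.1)
        val = gpr.kernel(np.array([0.0, 0.0]), np.array([1.0, 2.0]), th)
        assert val == pytest.approx(2.0 * np.exp(-(1.0 / 2.0 + 4.0 / 8.0)))

    def test_positive_hyperparameters_enforced(self):
        with pytest.raises(ValueError):
            gpr.Hyperparameters(0.0, np.array([1.0]), 0.1)

    def test_matrix_consistent_with_scalar(self, theta):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        K = gpr.kernel_matrix(X, X, theta)
        for i in range(6):
            for j in range(6):
                assert K[i, j] == pytest.approx(gpr.kernel(X[i], X[j], theta), abs=1e-12)


class TestMarginalLikelihood:
    def test_single_point_closed_form(self):
        th = gpr.Hyperparameters(2.0, np.array([1.0]), 0.5)
        val = gpr.neg_log_marginal_likelihood(th, np.array([[0.0]]), np.array([0.0]))
        expected = 0.5 * np.log(2.0 + 0.25) + 0.5 * np.log(2 * np.pi)
        assert val == pytest.approx(expected, rel=1e-12)

    def test_matches_dense_evaluation(self, theta):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        yc = y - y.mean()
        A = gpr.kernel_matrix(X, X, theta) + theta.sigma_n**2 * np.eye(5)
        expected = (
            0.5 * yc @ np.linalg.solve(A, yc)
            + 0.5 * np.linalg.slogdet(A)[1]
            + 2.5 * np.log(2 * np.pi)
        )
        assert gpr.neg_log_marginal_likelihood(theta, X, y) == pytest.approx(
            expected, rel=1e-10
        )

    @pytest.mark.parametrize("isotropic", [True, False])
    def test_gradient_matches_finite_differences(self, isotropic):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        yc = y - y.mean()
        nsb = 1 if isotropic else 3
        lt = np.log(np.concatenate(([1.5], np.full(nsb, 0.9), [0.3])))
        sq = gpr._squared_diffs(X, isotropic)
        _, grad = gpr._nlml_and_grad(lt, X, yc, isotropic, sq)
        for i in range(lt.size):
            e = np.zeros_like(lt)
            e[i] = 1e-6
            fd = (
                gpr._nlml_and_grad(lt + e, X, yc, isotropic, sq)[0]
                - gpr._nlml_and_grad(lt - e, X, yc, isotropic, sq)[0]
            ) / 2e-6
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestPredict:
    def test_two_point_hand_oracle(self):
        """2x2 system worked through explicit matrix arithmetic."""
        th = gpr.Hyperparameters(1.0, np.array([1.0]), 0.1)
        X = np.array([[0.0], [1.0]])
        y = np.array([1.0, 3.0])
        k01 = np.exp(-0.5)
        A = np.array([[1.01, k01], [k01, 1.01]])
        xs = np.array([[0.25]])
        ks = np.array([np.exp(-0.5 * 0.0625), np.exp(-0.5 * 0.5625)])
        yc = y - 2.0
        mean_o = ks @ np.linalg.solve(A, yc) + 2.0
        var_o = 1.0 - ks @ np.linalg.solve(A, ks)
        model = _model_from_theta(X, y, th)
        pred = gpr.predict(model, xs)
        assert pred.mean[0] == pytest.approx(mean_o, rel=1e-10)
        assert pred.variance[0] == pytest.approx(var_o, rel=1e-10)

    def test_noiseless_interpolation_at_training_points(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 4, size=(8, 2))
        y = np.sin(X[:, 0]) + X[:, 1]
        th = gpr.Hyperparameters(1.0, np.array([1.0]), 1e-6)
        model = _model_from_theta(X, y, th)
        pred = gpr.predict(model, X)
        np.testing.assert_allclose(pred.mean, y, atol=1e-4)
        assert np.all(pred.variance < 1e-4)

    def test_far_point_reverts_to_prior(self, theta):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10) + 5.0
        model = _model_from_theta(X, y, theta)
        pred = gpr.predict(model, np.full((1, 3), 500.0))
        assert pred.mean[0] == pytest.approx(model.y_offset, abs=1e-8)
        assert pred.variance[0] == pytest.approx(theta.nu, rel=1e-10)

    def test_variance_bounds_and_duplicate_monotonicity(self, theta):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        model = _model_from_theta(X, y, theta)
        Xs = rng.normal(size=(30, 3))
        var = gpr.predict(model, Xs, include_noise=True).variance
        assert np.all(var >= 0)
        assert np.all(var <= theta.nu + theta.sigma_n**2 + 1e-12)
        # duplicating a training point (same target) never increases variance
        X2 = np.vstack([X, X[0]])
        y2 = np.append(y, y[0])
        var2 = gpr.predict(_model_from_theta(X2, y2, theta), Xs, include_noise=True).variance
        assert np.all(var2 <= var + 1e-10)

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        th = gpr.Hyperparameters(1.0, np.array([0.7, 1.3, 0.9, 2.0]), 0.2)
        perm = [2, 0, 3, 1]
        th_p = gpr.Hyperparameters(1.0, th.sigma_b[perm], 0.2)
        Xs = rng.normal(size=(5, 4))
        p1 = gpr.predict(_model_from_theta(X, y, th), Xs)
        p2 = gpr.predict(_model_from_theta(X[:, perm], y, th_p), Xs[:, perm])
        np.testing.assert_allclose(p1.mean, p2.mean, atol=1e-10)
        np.testing.assert_allclose(p1.variance, p2.variance, atol=1e-10)

    def test_dimension_mismatch_rejected(self, theta):
        model = _model_from_theta(np.zeros((3, 3)) + np.eye(3), np.ones(3), theta)
        with pytest.raises(ValueError):
            gpr.predict(model, np.zeros((1, 2)))

    def test_agrees_with_sklearn_at_fixed_theta(self, theta):
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        Xs = rng.normal(size=(6, 3))
        k_sk = ConstantKernel(theta.nu, "fixed") * RBF(theta.sigma_b, "fixed") + WhiteKernel(
            theta.sigma_n**2, "fixed"
        )
        sk = GaussianProcessRegressor(kernel=k_sk, alpha=0.0, optimizer=None)
        sk.fit(X, y - y.mean())
        mean_sk, std_sk = sk.predict(Xs, return_std=True)
        pred = gpr.predict(_model_from_theta(X, y, theta), Xs, include_noise=True)
        np.testing.assert_allclose(pred.mean, mean_sk + y.mean(), atol=1e-10)
        np.testing.assert_allclose(pred.variance, std_sk**2, atol=1e-8)


class TestFit:
    def test_constant_target_reproduced(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 2))
        y = np.full(12, 7.5)
        model = gpr.fit(X, y, kernel_mode="isotropic", n_restarts=2, seed=0)
        pred = gpr.predict(model, rng.normal(size=(5, 2)))
        np.testing.assert_allclose(pred.mean, 7.5, atol=1e-3)

    def test_optimizer_never_worse_than_starts(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 5, size=(30, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=30)
        model = gpr.fit(X, y, kernel_mode="isotropic", n_restarts=3, seed=1)
        start = gpr._initial_theta(X, y, True)
        assert model.nlml <= gpr.neg_log_marginal_likelihood(start, X, y) + 1e-9

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        a = gpr.fit(X, y, n_restarts=3, seed=5)
        b = gpr.fit(X, y, n_restarts=3, seed=5)
        assert a.theta.nu == b.theta.nu
        assert np.array_equal(a.theta.sigma_b, b.theta.sigma_b)
        assert np.array_equal(a.alpha, b.alpha)

    def test_hyperparameter_recovery_single_draw(self):
        """A long draw from a known GP recovers log-hyperparameters closely."""
        rng = np.random.default_rng(12)
        true = gpr.Hyperparameters(1.0, np.array([1.0]), 0.1)
        X = rng.uniform(0, 10, size=(200, 2))
        K = gpr.kernel_matrix(X, X, true) + true.sigma_n**2 * np.eye(200)
        y = np.linalg.cholesky(K) @ rng.normal(size=200)
        model = gpr.fit(X, y, kernel_mode="isotropic", n_restarts=3, seed=2)
        assert abs(np.log(model.theta.sigma_b[0])) < 0.3
        assert abs(np.log(model.theta.sigma_n) - np.log(0.1)) < 0.3

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            gpr.fit(np.zeros((1, 2)), np.zeros(1))


class TestGoodnessOfFit:
    def test_perfect_and_mean_predictions(self):
        o = np.array([1.0, 2.0, 4.0, 7.0])
        perfect = gpr.goodness_of_fit(o, o)
        assert perfect.rmse == 0.0 and perfect.r2 == 1.0
        at_mean = gpr.goodness_of_fit(np.full(4, o.mean()), o)
        assert at_mean.r2 == pytest.approx(0.0, abs=1e-12)

    def test_range_normalization_convention(self):
        """RMSE 3.26 over an observed range 0.9-21.5 gives NRMSE ~15.8%."""
        o = np.array([0.9, 21.5, 10.0, 15.0])
        p = o + 3.26
        m = gpr.goodness_of_fit(p, o)
        assert m.rmse == pytest.approx(3.26, rel=1e-12)
        assert m.nrmse == pytest.approx(100 * 3.26 / 20.6, rel=1e-12)
        assert m.nrmse == pytest.approx(15.88, abs=0.1)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError):
            gpr.goodness_of_fit(np.array([1.0, 2.0]), np.array([3.0, 3.0]))
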