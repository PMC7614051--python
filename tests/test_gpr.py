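import numpy as np
import pytest

from s1lai import gpr


def dense_predict(X, y, Xs, theta, alpha_0):
    """Independent dense-inverse oracle for GP mean and SD."""
    K = gpr._kernel_matrix(X, X, theta)
    C = K + theta.sigma_n ** 2 * np.eye(len(y))
    Ks = gpr._kernel_matrix(Xs, X, theta)
    Cinv = np.linalg.inv(C)
    mean = Ks @ Cinv @ (y - alpha_0) + alpha_0
    var = theta.v + theta.sigma_n ** 2 - np.einsum(
        "mn,nm->m", Ks, Cinv @ Ks.T)
    return mean, np.sqrt(np.maximum(var, 0))


def fixed_theta_model(X, y, theta):
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    m = gpr.GPRModel(theta, None, float(y.mean()), X,
                     np.zeros(X.shape[1]), np.ones(X.shape[1]),
                     [f"b{i}" for i in range(X.shape[1])], y)
    K = gpr._kernel_matrix(X, X, theta)
    C = K + theta.sigma_n ** 2 * np.eye(len(y))
    m.alpha = np.linalg.solve(C, y - y.mean())
    return m


class TestKernel:
    def test_same_point_with_noise(self):
        th = gpr.Hyperparams(2.0, 0.5, np.array([1.0, 1.0]))
        x = np.array([1.0, 2.0])
        assert gpr.ard_kernel(x, x, th, same_index=True) == pytest.approx(2.25)

    def test_unit_distance_value(self):
        th = gpr.Hyperparams(1.0, 0.1, np.array([1.0]))
        val = gpr.ard_kernel(np.array([0.0]), np.array([np.sqrt(2.0)]), th)
        assert val == pytest.approx(np.exp(-1), rel=1e-12)

    def test_decay_and_symmetry(self, rng):
        th = gpr.Hyperparams(1.5, 0.2, np.array([0.5, 2.0, 1.0]))
        a, b = rng.normal(size=3), rng.normal(size=3)
        assert gpr.ard_kernel(a, b, th) == pytest.approx(gpr.ard_kernel(b, a, th))
        far = a + 1e4
        assert gpr.ard_kernel(a, far, th) < 1e-12

    def test_length_mismatch_rejected(self):
        th = gpr.Hyperparams(1.0, 0.1, np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            gpr.ard_kernel(np.zeros(2), np.zeros(3), th)


class TestPredict:
    def test_matches_dense_inverse(self, rng):
        th = gpr.Hyperparams(2.0, 0.3, np.array([1.0, 0.7, 2.0]))
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        Xs = rng.normal(size=(5, 3))
        m = fixed_theta_model(X, y, th)
        p = gpr.predict(m, Xs)
        mean_d, sd_d = dense_predict(X, y, Xs, th, y.mean())
        assert np.allclose(p.mean, mean_d, atol=1e-10)
        assert np.allclose(p.sd, sd_d, atol=1e-10)

    def test_interpolates_labels_at_small_noise(self, rng):
        th = gpr.Hyperparams(1.0, 1e-6, np.array([1.0, 1.0]))
        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        m = fixed_theta_model(X, y, th)
        p = gpr.predict(m, X)
        assert np.allclose(p.mean, y, atol=1e-6)

    def test_far_points_revert_to_prior(self, rng):
        th = gpr.Hyperparams(1.3, 0.2, np.array([1.0]))
        X = rng.normal(size=(6, 1))
        y = rng.normal(size=6) + 3.0
        m = fixed_theta_model(X, y, th)
        p = gpr.predict(m, X + 1e5)
        assert np.allclose(p.mean, y.mean(), atol=1e-8)
        assert np.allclose(p.sd, np.sqrt(th.v + th.sigma_n ** 2), atol=1e-8)

    def test_sd_bounded_and_smaller_at_training_points(self, rng):
        th = gpr.Hyperparams(2.0, 0.3, np.array([1.0]))
        X = rng.normal(size=(10, 1))
        y = rng.normal(size=10)
        m = fixed_theta_model(X, y, th)
        near = gpr.predict(m, X)
        far = gpr.predict(m, X + 10.0)   # 10 length scales away
        cap = np.sqrt(th.v + th.sigma_n ** 2) + 1e-8
        assert np.all(near.sd <= cap) and np.all(far.sd <= cap)
        assert np.all(near.sd <= far.sd + 1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        th = gpr.Hyperparams(1.0, 0.1, np.array([1.0, 1.0]))
        m = fixed_theta_model(rng.normal(size=(5, 2)), rng.normal(size=5), th)
        with pytest.raises(ValueError):
            gpr.predict(m, rng.normal(size=(3, 4)))

    def test_matches_sklearn_reference(self, rng):
        """Cross-check against an independent GP implementation."""
        sklearn_gp = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process.kernels import (RBF, ConstantKernel,
                                                      WhiteKernel)
        th = gpr.Hyperparams(1.8, 0.25, np.array([0.9, 1.4]))
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        Xs = rng.normal(size=(6, 2))
        m = fixed_theta_model(X, y, th)
        p = gpr.predict(m, Xs)
        kern = (ConstantKernel(th.v, "fixed")
                * RBF(th.sigma_b, "fixed")
                + WhiteKernel(th.sigma_n ** 2, "fixed"))
        ref = sklearn_gp.GaussianProcessRegressor(
            kernel=kern, optimizer=None, alpha=0.0).fit(X, y - y.mean())
        mean_ref, sd_ref = ref.predict(Xs, return_std=True)
        assert np.allclose(p.mean, mean_ref + y.mean(), atol=1e-8)
        assert np.allclose(p.sd, sd_ref, atol=1e-8)


class TestFit:
    def test_constant_labels_degenerate(self, rng):
        X = rng.normal(size=(10, 2))
        m = gpr.fit(X, np.full(10, 2.5), seed=0)
        assert m.degenerate
        p = gpr.predict(m, rng.normal(size=(4, 2)))
        assert np.allclose(p.mean, 2.5)

    def test_learns_smooth_function(self, rng):
        X = rng.uniform(-3, 3, size=(60, 2))
        y = np.sin(X[:, 0]) + 2.0 + 0.02 * rng.normal(size=60)
        m = gpr.fit(X, y, seed=1)
        Xt = rng.uniform(-2.5, 2.5, size=(100, 2))
        p = gpr.predict(m, Xt)
        rmse = np.sqrt(np.mean((p.mean - (np.sin(Xt[:, 0]) + 2.0)) ** 2))
        assert rmse < 0.15

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(25, 3))
        y = X[:, 0] ** 2 + 0.1 * rng.normal(size=25)
        m1 = gpr.fit(X, y, seed=7)
        m2 = gpr.fit(X, y, seed=7)
        assert np.array_equal(m1.alpha, m2.alpha)
        assert m1.theta.sigma_b.tolist() == m2.theta.sigma_b.tolist()

    def test_active_feature_ranked_first(self, rng):
        X = rng.uniform(-2, 2, size=(40, 2))
        y = np.sin(2 * X[:, 0]) + 0.05 * rng.normal(size=40)
        m = gpr.fit(X, y, seed=3)
        ranking = gpr.feature_relevance(m)
        assert ranking[0][0] == "band0"

    def test_column_permutation_permutes_ranking(self, rng):
        X = rng.uniform(-2, 2, size=(35, 3))
        y = np.cos(X[:, 1]) + 0.05 * rng.normal(size=35)
        m = gpr.fit(X, y, seed=5, band_names=["a", "b", "c"])
        perm = [2, 0, 1]
        m2 = gpr.fit(X[:, perm], y, seed=5, band_names=["c", "a", "b"])
        assert [t for t, _ in gpr.feature_relevance(m)] == \
            [t for t, _ in gpr.feature_relevance(m2)]


class TestRelevanceAndSerialization:
    def test_reciprocal_ordering(self):
        th = gpr.Hyperparams(1.0, 0.1, np.array([1.0, 2.0, 4.0]))
        m = gpr.GPRModel(th, np.zeros(2), 0.0, np.zeros((2, 3)),
                         np.zeros(3), np.ones(3), ["x", "y", "z"],
                         np.zeros(2))
        assert gpr.feature_relevance(m) == [("x", 1.0), ("y", 0.5),
                                            ("z", 0.25)]

    def test_roundtrip_preserves_predictions(self, rng, tmp_path):
        X = rng.normal(size=(20, 2))
        y = X[:, 0] + 0.1 * rng.normal(size=20)
        m = gpr.fit(X, y, seed=0)
        gpr.save_model(m, tmp_path / "model.json")
        m2 = gpr.load_model(tmp_path / "model.json")
        Xs = rng.normal(size=(7, 2))
        p1, p2 = gpr.predict(m, Xs), gpr.predict(m2, Xs)
        assert np.allclose(p1.mean, p2.mean, atol=1e-12)
        assert np.allclose(p1.sd, p2.sd, atol=1e-12)
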