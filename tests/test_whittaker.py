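import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from s1lai import whittaker as wt


def dense_solution(y, w, lam, p):
    """Independent dense normal-equation oracle for the smoother."""
    n = y.size
    M = wt.difference_matrix(n, p).toarray()
    A = lam * np.diag(w) + M.T @ M
    return np.linalg.solve(A, lam * w * y)


class TestDifferenceMatrix:
    def test_order2_n6(self):
        expected = np.array([
            [1, -2, 1, 0, 0, 0],
            [0, 1, -2, 1, 0, 0],
            [0, 0, 1, -2, 1, 0],
            [0, 0, 0, 1, -2, 1]], dtype=float)
        assert np.array_equal(wt.difference_matrix(6, 2).toarray(), expected)

    @pytest.mark.parametrize("n,p,coeffs", [
        (4, 1, [-1, 1]),
        (5, 3, [-1, 3, -3, 1]),
        (7, 4, [1, -4, 6, -4, 1]),
    ])
    def test_binomial_rows(self, n, p, coeffs):
        M = wt.difference_matrix(n, p).toarray()
        assert M.shape == (n - p, n)
        for j in range(n - p):
            row = M[j, j:j + p + 1]
            # rows may differ from the reference by a global sign only
            assert (np.array_equal(row, coeffs)
                    or np.array_equal(-row, coeffs))
            assert np.all(M[j, :j] == 0) and np.all(M[j, j + p + 1:] == 0)

    def test_rejects_p_ge_n(self):
        with pytest.raises(ValueError):
            wt.difference_matrix(3, 3)


class TestSmoothFixed:
    def test_constant_series_unchanged(self, rng):
        s = wt.WeightedSeries(np.full(11, 3.7))
        for lam in (1e-3, 1.0, 1e3):
            assert np.allclose(wt.smooth_fixed(s, lam, 2).x_hat, 3.7)

    def test_linear_series_exact_for_p2(self):
        y = 2.0 + 1.5 * np.arange(9)
        res = wt.smooth_fixed(wt.WeightedSeries(y), 0.37, 2)
        assert np.allclose(res.x_hat, y, atol=1e-9)

    def test_matches_dense_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 51))
            y = rng.normal(size=n)
            w = rng.uniform(0.1, 1.0, size=n)
            lam = 10.0 ** rng.uniform(-3, 3)
            got = wt.smooth_fixed(wt.WeightedSeries(y, w), lam, 2).x_hat
            ref = dense_solution(y, w, lam, 2)
            assert np.max(np.abs(got - ref)) <= 1e-8 * max(1, np.max(np.abs(ref)))

    def test_large_lambda_reproduces_data(self, rng):
        y = rng.normal(size=15)
        res = wt.smooth_fixed(wt.WeightedSeries(y), 1e10, 2)
        assert np.allclose(res.x_hat, y, atol=1e-5)

    def test_small_lambda_tends_to_polynomial(self, rng):
        y = rng.normal(size=25)
        res = wt.smooth_fixed(wt.WeightedSeries(y), 1e-12, 2)
        t = np.arange(25)
        coef = np.polyfit(t, y, 1)
        assert np.allclose(res.x_hat, np.polyval(coef, t), atol=1e-4)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            wt.smooth_fixed(wt.WeightedSeries(np.ones(6), np.zeros(6)), 1.0, 2)

    def test_multi_rhs_agrees_with_single(self, rng):
        Y = rng.normal(size=(20, 5))
        w = (rng.uniform(size=20) > 0.3).astype(float)
        w[:3] = 1.0
        X = wt.smooth_fixed_multi(Y, w, 2.5, 2)
        for j in range(5):
            y = np.where(w > 0, Y[:, j], 0.0)
            single = wt.smooth_fixed(wt.WeightedSeries(y, w), 2.5, 2).x_hat
            assert np.allclose(X[:, j], single, atol=1e-10)


@settings(max_examples=25, deadline=None)
@given(hst.lists(hst.floats(-50, 50), min_size=5, max_size=30),
       hst.floats(-2, 2))
def test_moment_preservation_uniform_weights(values, log_lam):
    """With uniform weights and p = 2, Σx̂ and Σj·x̂_j match the data."""
    y = np.asarray(values)
    res = wt.smooth_fixed(wt.WeightedSeries(y), 10.0 ** log_lam, 2)
    j = np.arange(1, y.size + 1)
    scale = max(1.0, np.abs(y).sum())
    assert abs(res.x_hat.sum() - y.sum()) <= 1e-8 * scale
    assert abs((j * res.x_hat).sum() - (j * y).sum()) <= 1e-7 * scale * y.size


class TestGCV:
    def test_constant_series_scores_zero(self):
        s = wt.WeightedSeries(np.full(9, 1.2))
        assert wt.gcv_score(s, 5.0, 2) < 1e-20

    def test_matches_dense_inverse_oracle(self, rng):
        y = rng.normal(size=8)
        s = wt.WeightedSeries(y)
        lam = 10.0
        M = wt.difference_matrix(8, 2).toarray()
        H = lam * np.linalg.inv(lam * np.eye(8) + M.T @ M)
        x_hat = H @ y
        expected = np.mean(((y - x_hat) / (1 - np.trace(H) / 8)) ** 2)
        assert abs(wt.gcv_score(s, lam, 2) - expected) < 1e-10

    def test_solution_forms_agree(self, rng):
        # x̂ from the normal equations equals (I + λ⁻¹MᵀM)⁻¹y
        y = rng.normal(size=12)
        lam = 3.0
        M = wt.difference_matrix(12, 2).toarray()
        alt = np.linalg.solve(np.eye(12) + M.T @ M / lam, y)
        got = wt.smooth_fixed(wt.WeightedSeries(y), lam, 2).x_hat
        assert np.allclose(got, alt, atol=1e-10)

    def test_gcv_selection_denoises(self, rng):
        t = np.arange(90)
        truth = np.sin(2 * np.pi * t / 45)
        y = truth + rng.normal(0, 0.4, t.size)
        res = wt.gcv_select(wt.WeightedSeries(y))
        assert (np.sqrt(np.mean((res.x_hat - truth) ** 2))
                < np.sqrt(np.mean((y - truth) ** 2)))


class TestVCurve:
    def test_smallest_grid_returns_interval_midpoint(self, rng):
        y = rng.normal(size=20)
        res = wt.vcurve_select(wt.WeightedSeries(y), 2, (-1.0, 0.0, 0.5))
        assert np.log10(res.lam) in (-0.75, -0.25)
        assert res.method == "vcurve"
        assert res.curve is not None and len(res.curve) == 3

    def test_denoises_noisy_sinusoid(self, rng):
        t = np.arange(100)
        truth = 2.0 * np.sin(2 * np.pi * t / 50)
        y = truth + rng.normal(0, 0.5, t.size)
        res = wt.vcurve_select(wt.WeightedSeries(y))
        assert (np.sqrt(np.mean((res.x_hat - truth) ** 2))
                < np.sqrt(np.mean((y - truth) ** 2)))

    def test_selected_lambda_near_truth_optimal(self):
        """V-curve λ within two 0.25-dex grid steps of the brute-force
        truth-RMSE minimizer in ≥80% of replicates."""
        rng = np.random.default_rng(0)
        step = 0.25
        exps = np.arange(-4, 4 + step / 2, step)
        hits = 0
        for _ in range(100):
            t = np.arange(100)
            truth = rng.uniform(1, 3) * np.sin(
                2 * np.pi * t / rng.uniform(30, 60) + rng.uniform(0, 6))
            y = truth + rng.normal(0, 0.5, t.size)
            s = wt.WeightedSeries(y)
            res = wt.vcurve_select(s, 2, (-4.0, 4.0, step))
            rmse = [np.sqrt(np.mean((wt.smooth_fixed(s, 10.0 ** e, 2).x_hat
                                     - truth) ** 2)) for e in exps]
            best = exps[int(np.argmin(rmse))]
            hits += abs(np.log10(res.lam) - best) <= 2 * step + 1e-9
        assert hits >= 80

    def test_zero_residual_fallback_warns(self, monkeypatch):
        # a degenerate (ψ, φ) curve (exact zero residual and roughness at
        # every λ) triggers the fidelity-dominant fallback with a warning
        def degenerate_points(series, p, exps):
            return (np.full(exps.size, -np.inf), np.full(exps.size, -np.inf))

        monkeypatch.setattr(wt, "vcurve_points", degenerate_points)
        y = np.full(10, 2.0)
        res = wt.vcurve_select(wt.WeightedSeries(y), 2, (-1.0, 1.0, 0.5))
        assert res.lam == pytest.approx(10.0)   # fidelity-dominant grid end
        assert np.allclose(res.x_hat, y, atol=1e-6)
        assert res.warnings


class TestInterpolation:
    def test_daily_linear_observations_reproduced(self):
        grid = np.arange(30)
        y = 0.3 * grid + 1.0
        res = wt.smooth_interpolate(grid, y, grid, method="vcurve")
        assert np.allclose(res.x_hat, y, atol=1e-6)

    def test_sparse_cadence_recovers_smooth_curve(self, rng):
        grid = np.arange(120)
        truth = 2.0 + 1.5 * np.sin(2 * np.pi * grid / 120)
        obs = grid[::12]
        noise_sd = 0.15
        res = wt.smooth_interpolate(obs, truth[obs] + rng.normal(0, noise_sd,
                                                                 obs.size),
                                    grid)
        mid = grid[6:-6:12]          # mid-cycle days between observations
        assert np.max(np.abs(res.x_hat[mid] - truth[mid])) < 3 * noise_sd * 3

    def test_observation_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            wt.smooth_interpolate(np.array([0, 200]), np.array([1.0, 2.0]),
                                  np.arange(100))

    def test_weight_removal_equals_direct_resolve(self, rng):
        grid = np.arange(40)
        obs = grid[::4]
        vals = np.cos(obs / 6.0) + rng.normal(0, 0.05, obs.size)
        full = wt.smooth_interpolate(obs, vals, grid, method="fixed", lam=1.0)
        # drop one interior observation, compare against direct re-solve
        keep = np.ones(obs.size, dtype=bool)
        keep[4] = False
        dropped = wt.smooth_interpolate(obs[keep], vals[keep], grid,
                                        method="fixed", lam=1.0)
        y = np.zeros(grid.size)
        w = np.zeros(grid.size)
        y[obs] = vals
        w[obs] = 1.0
        w[obs[4]] = 0.0
        direct = wt.smooth_fixed(wt.WeightedSeries(y, w), 1.0, 2).x_hat
        assert np.allclose(dropped.x_hat, direct, atol=1e-10)
        assert np.max(np.abs(full.x_hat - dropped.x_hat)) <= \
            np.max(np.abs(full.x_hat - direct)) + 1e-12
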