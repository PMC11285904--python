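"""Distribution distances: closed-form oracles, symmetry, additivity."""

import numpy as np
import pytest

import fatescape as fs
from fatescape.distances import SinkhornConvergenceError, median_bandwidth


def gaussian_kernel_expectation(m1, m2, cov_sum, sigma, d):
    """E[k(x, y)] for x ~ N(m1, S1), y ~ N(m2, S2) under a Gaussian
    kernel with bandwidth sigma; cov_sum = S1 + S2 (isotropic c * I)."""
    c = cov_sum + sigma**2
    delta2 = float(np.sum((np.asarray(m1) - np.asarray(m2)) ** 2))
    return (sigma**2 / c) ** (d / 2) * np.exp(-delta2 / (2 * c))


class TestMMD:
    def test_identical_point_masses_zero(self):
        X = np.tile([1.0, 2.0], (6, 1))
        assert fs.mmd2_unbiased(X, X.copy(), sigma=1.0) == 0.0

    def test_two_point_masses_closed_form(self):
        x, y, sigma = np.array([0.0, 0.0]), np.array([3.0, 4.0]), 2.0
        X = np.tile(x, (5, 1))
        Y = np.tile(y, (7, 1))
        expected = 2 * (1 - np.exp(-25.0 / (2 * sigma**2)))
        assert fs.mmd2_unbiased(X, Y, sigma=sigma) == pytest.approx(expected, rel=1e-12)

    def test_gaussian_population_value(self, rng):
        # closed form: population MMD^2 between N(0, I2) and N(mu, I2)
        # from analytic Gaussian-kernel integrals
        n, sigma = 2000, 1.5
        mu = np.array([1.0, 0.5])
        X = rng.standard_normal((n, 2))
        Y = rng.standard_normal((n, 2)) + mu
        exx = gaussian_kernel_expectation(0, 0, 2.0, sigma, 2)
        eyy = exx
        exy = gaussian_kernel_expectation([0, 0], mu, 2.0, sigma, 2)
        pop = exx + eyy - 2 * exy
        est = fs.mmd2_unbiased(X, Y, sigma=sigma)
        # bootstrap standard error of the estimator
        boots = []
        for _ in range(40):
            i = rng.integers(0, n, n)
            j = rng.integers(0, n, n)
            boots.append(fs.mmd2_unbiased(X[i][:400], Y[j][:400], sigma=sigma))
        se = np.std(boots, ddof=1)
        assert abs(est - pop) < 3 * se

    def test_symmetry(self, rng):
        X, Y = rng.normal(size=(40, 3)), rng.normal(size=(50, 3))
        assert fs.mmd2_unbiased(X, Y) == fs.mmd2_unbiased(Y, X)

    def test_median_heuristic_is_half_pooled_median(self, rng):
        from scipy.spatial.distance import pdist

        X, Y = rng.normal(size=(30, 2)), rng.normal(size=(20, 2))
        assert median_bandwidth(X, Y) == pytest.approx(
            np.median(pdist(np.vstack([X, Y]))) / 2
        )

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            fs.mmd2_unbiased(np.zeros((1, 2)), np.zeros((5, 2)), sigma=1.0)
        with pytest.raises(ValueError):
            fs.mmd2_unbiased(np.zeros((5, 2)), np.zeros((5, 2)), sigma=-1.0)


class TestSinkhorn:
    def test_self_divergence_zero(self, rng):
        X = rng.normal(size=(30, 4))
        assert abs(fs.sinkhorn_divergence(X, X.copy())) <= 1e-8

    def test_single_atoms_recover_squared_distance(self):
        # point masses: the divergence is the raw transport cost
        val = fs.sinkhorn_divergence(
            np.array([[0.0]]), np.array([[2.0]]), epsilon=0.01, scale=None
        )
        assert val == pytest.approx(4.0, rel=0.01)

    def test_1d_matches_sorted_quantile_w2(self, rng):
        X = rng.normal(0, 1, size=(50, 1))
        Y = rng.normal(0.7, 1.3, size=(50, 1))
        exact = float(np.mean((np.sort(X.ravel()) - np.sort(Y.ravel())) ** 2))
        val = fs.sinkhorn_divergence(X, Y, epsilon=0.05, scale=None)
        assert val == pytest.approx(exact, rel=0.05)

    def test_entropic_bias_vanishes_as_eps_decreases(self, rng):
        X = rng.normal(0, 1, size=(25, 1))
        Y = rng.normal(1.0, 1, size=(25, 1))
        exact = float(np.mean((np.sort(X.ravel()) - np.sort(Y.ravel())) ** 2))
        errs = [
            abs(fs.sinkhorn_divergence(X, Y, epsilon=e, scale=None, tol=1e-6) - exact)
            for e in (0.8, 0.2, 0.05)
        ]
        assert errs[2] < errs[0]
        assert errs[2] < 0.05 * exact

    def test_symmetry(self, rng):
        X, Y = rng.normal(size=(20, 2)), rng.normal(1, 1, size=(25, 2))
        a = fs.sinkhorn_divergence(X, Y, epsilon=0.1, tol=1e-8)
        b = fs.sinkhorn_divergence(Y, X, epsilon=0.1, tol=1e-8)
        assert a == pytest.approx(b, abs=1e-8)

    def test_invalid_epsilon(self, rng):
        with pytest.raises(ValueError):
            fs.sinkhorn_divergence(np.zeros((3, 1)), np.ones((3, 1)), epsilon=-1)

    def test_nonconvergence_carries_residual(self, rng):
        X, Y = rng.normal(size=(30, 2)), rng.normal(5, 1, size=(30, 2))
        with pytest.raises(SinkhornConvergenceError) as exc:
            fs.sinkhorn_divergence(X, Y, epsilon=0.01, scale=None, max_iter=2,
                                   tol=1e-12)
        assert exc.value.residual > 0


class TestBhattacharyya:
    def test_identical_distributions_near_zero(self, rng):
        X = rng.standard_normal((500, 1))
        Y = rng.standard_normal((500, 1))
        assert fs.bhattacharyya_kde(X, Y) <= 0.02

    def test_gaussian_closed_form(self, rng):
        # B(N(0,1), N(2,1)) = (mu1 - mu2)^2 / 8 = 0.5
        n = 5000
        X = rng.standard_normal((n, 1))
        Y = rng.standard_normal((n, 1)) + 2.0
        val = fs.bhattacharyya_kde(X, Y)
        assert val == pytest.approx(0.5, rel=0.15)

    def test_swap_symmetry(self, rng):
        X, Y = rng.normal(size=(60, 2)), rng.normal(1, 2, size=(70, 2))
        assert fs.bhattacharyya_kde(X, Y) == pytest.approx(
            fs.bhattacharyya_kde(Y, X), abs=1e-12
        )

    def test_degenerate_dimension_warns_not_raises(self, rng):
        X = np.column_stack([rng.normal(size=50), np.zeros(50)])
        Y = rng.normal(size=(50, 2))
        with pytest.warns(RuntimeWarning):
            val = fs.bhattacharyya_kde(X, Y)
        assert np.isfinite(val)


class TestSnapshotDistance:
    @pytest.fixture(scope="class")
    def pair(self, true_params):
        a = fs.simulate_dataset(true_params, n_cells=40, seed=1)
        b = fs.simulate_dataset(true_params, n_cells=40, seed=2)
        return a, b

    @pytest.mark.parametrize("metric", ["mmd", "sinkhorn", "bhattacharyya",
                                        "euclidean_summary"])
    def test_self_distance_zero(self, pair, metric):
        a, _ = pair
        same = fs.SnapshotDataset(a.values.copy(), a.time_grid.copy())
        assert fs.snapshot_distance(a, same, metric=metric) <= 1e-7

    @pytest.mark.parametrize("metric", ["mmd", "sinkhorn", "bhattacharyya"])
    def test_single_time_point_equals_base_metric(self, pair, metric):
        a, b = pair
        a1 = fs.SnapshotDataset(a.values[:, -1:, :], a.time_grid[-1:])
        b1 = fs.SnapshotDataset(b.values[:, -1:, :], b.time_grid[-1:])
        total = fs.snapshot_distance(a1, b1, metric=metric)
        base = {
            "mmd": lambda: max(fs.mmd2_unbiased(a1.slice_at(0), b1.slice_at(0)), 0),
            "sinkhorn": lambda: fs.sinkhorn_divergence(a1.slice_at(0), b1.slice_at(0)),
            "bhattacharyya": lambda: fs.bhattacharyya_kde(a1.slice_at(0), b1.slice_at(0)),
        }[metric]()
        assert total == pytest.approx(base, abs=1e-9)

    def test_additivity_over_time_splits(self, pair):
        a, b = pair
        total = fs.snapshot_distance(a, b, metric="mmd")
        first = fs.SnapshotDataset(a.values[:, :5, :], a.time_grid[:5])
        second = fs.SnapshotDataset(a.values[:, 5:, :], a.time_grid[5:])
        bf = fs.SnapshotDataset(b.values[:, :5, :], b.time_grid[:5])
        bs = fs.SnapshotDataset(b.values[:, 5:, :], b.time_grid[5:])
        split = fs.snapshot_distance(first, bf, metric="mmd") + fs.snapshot_distance(
            second, bs, metric="mmd"
        )
        assert total == pytest.approx(split, abs=1e-12)

    def test_mismatched_grids_rejected(self, pair):
        a, b = pair
        short = fs.SnapshotDataset(b.values[:, :5, :], b.time_grid[:5])
        with pytest.raises(ValueError):
            fs.snapshot_distance(a, short, metric="mmd")

    def test_unknown_metric_rejected(self, pair):
        a, b = pair
        with pytest.raises(ValueError):
            fs.snapshot_distance(a, b, metric="hausdorff")
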