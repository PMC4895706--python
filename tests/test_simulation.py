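"""Simulation generators, the max-type comparator, and ROC mechanics."""

import numpy as np
import pytest

from netcov.simulate import (
    CovModelSpec,
    MAModelSpec,
    cai_max_statistic,
    power_ma_models,
    roc_curve,
    simulate_cov_model,
    simulate_ma_model,
)


class TestMAModels:
    @pytest.mark.parametrize("model", [1, 2, 3])
    def test_shape(self, model):
        X = simulate_ma_model(MAModelSpec(model=model, p=7, n=12, theta=0.5, seed=1))
        assert X.shape == (12, 7)

    def test_theta_zero_gives_identity_covariance(self):
        X = simulate_ma_model(MAModelSpec(model=1, p=10, n=100_000, theta=0.0, seed=2))
        S = np.cov(X, rowvar=False)
        off = S - np.diag(np.diag(S))
        assert np.abs(off).max() < 0.05
        assert np.abs(np.diag(S) - 1.0).max() < 0.05

    def test_model1_tridiagonal_covariance(self):
        theta = 0.5
        X = simulate_ma_model(MAModelSpec(model=1, p=10, n=100_000, theta=theta, seed=3))
        S = np.cov(X, rowvar=False)
        expected = np.zeros((10, 10))
        np.fill_diagonal(expected, 1 + theta**2)
        idx = np.arange(9)
        expected[idx, idx + 1] = theta
        expected[idx + 1, idx] = theta
        assert np.abs(S - expected).max() < 0.05

    def test_deterministic_given_seed(self):
        spec = MAModelSpec(model=2, p=5, n=20, theta=0.3, seed=9)
        np.testing.assert_array_equal(simulate_ma_model(spec), simulate_ma_model(spec))

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            MAModelSpec(model=4, p=5, n=10, theta=0.5)


class TestCovModels:
    @pytest.mark.parametrize("model", [1, 2, 3, 4])
    def test_construction_invariants(self, model):
        spec = CovModelSpec(model=model, p=30, n_per_class=10, seed=model)
        X1, X2, S1, S2 = simulate_cov_model(spec)
        assert X1.shape == (10, 30) and X2.shape == (10, 30)
        # positive definiteness forced by the delta shift
        assert np.linalg.eigvalsh(S1)[0] >= 0.05 - 1e-9
        assert np.linalg.eigvalsh(S2)[0] >= 0.05 - 1e-9
        # Sigma1 - Sigma2 = -U with the stated sparsity
        U = S2 - S1
        np.testing.assert_allclose(U, U.T)
        assert np.count_nonzero(U) == spec.n_nonzero

    def test_ar_base_structure(self):
        """Off-diagonals of Sigma1 carry no delta shift, so they must equal
        sqrt(d_i d_j) * 0.5^|i-j|; in particular the two-step base
        correlation is 0.5^2 = 0.25."""
        spec = CovModelSpec(model=1, p=6, n_per_class=10, seed=5)
        _, _, S1, _ = simulate_cov_model(spec, rng=np.random.default_rng(5))
        d = np.random.default_rng(5).uniform(0.5, 2.5, size=6)  # first draw of the generator
        scale = np.sqrt(np.outer(d, d))
        idx = np.arange(6)
        expected = scale * 0.5 ** np.abs(idx[:, None] - idx[None, :])
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(S1[off], expected[off], rtol=1e-10)
        assert S1[0, 2] / scale[0, 2] == pytest.approx(0.25)

    def test_odd_nonzero_count_rejected_when_mirrored_counts_twice(self):
        from netcov.simulate import _symmetric_perturbation

        with pytest.raises(ValueError, match="even"):
            _symmetric_perturbation(
                10, 7, 4.0, 1.0, np.random.default_rng(0), count_mirrored_once=False
            )

    def test_mirrored_once_doubles_cells(self):
        spec = CovModelSpec(model=1, p=30, n_per_class=10, seed=6, count_mirrored_once=True)
        _, _, S1, S2 = simulate_cov_model(spec)
        assert np.count_nonzero(S2 - S1) == 2 * spec.n_nonzero


class TestCaiMaxStatistic:
    def test_identical_groups_give_zero_and_p_one(self, rng):
        X = rng.standard_normal((20, 10))
        stat, p = cai_max_statistic(X, X.copy())
        assert stat == 0.0
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_statistic_dominates_any_single_entry(self, rng):
        X1 = rng.standard_normal((20, 6))
        X2 = rng.standard_normal((20, 6))
        stat, _ = cai_max_statistic(X1, X2)

        def entry_stat(i, j):
            def one(X):
                Xc = X - X.mean(0)
                S = Xc.T @ Xc / X.shape[0]
                th = ((Xc[:, i] * Xc[:, j] - S[i, j]) ** 2).mean()
                return S[i, j], th

            s1, t1 = one(X1)
            s2, t2 = one(X2)
            return (s1 - s2) ** 2 / (t1 / 20 + t2 / 20)

        for i, j in [(0, 0), (1, 4), (2, 3)]:
            assert stat >= entry_stat(i, j) - 1e-12

    def test_null_calibration_rough(self):
        """Gaussian H0 at p=50, n=50: the extreme-value test is known to be
        conservative-to-nominal at this size."""
        rng = np.random.default_rng(15)
        rejections = 0
        reps = 200
        for _ in range(reps):
            X1 = rng.standard_normal((50, 50))
            X2 = rng.standard_normal((50, 50))
            _, p = cai_max_statistic(X1, X2)
            rejections += p <= 0.05
        assert 0.0 <= rejections / reps <= 0.10

    def test_too_small_groups_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            cai_max_statistic(rng.standard_normal((4, 3)), rng.standard_normal((10, 3)))


class TestROC:
    def test_identical_distributions_give_diagonal(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        curve = roc_curve(v, v.copy())
        np.testing.assert_allclose(curve.fpr, curve.tpr)
        assert curve.auc() == pytest.approx(0.5)

    def test_perfect_separation(self):
        curve = roc_curve(np.array([1.0, 2.0]), np.array([5.0, 6.0]))
        assert curve.auc() == pytest.approx(1.0)
        assert any((f == 0.0 and t == 1.0) for f, t in zip(curve.fpr, curve.tpr))

    def test_four_value_toy_enumeration(self):
        curve = roc_curve(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        pts = list(zip(curve.fpr, curve.tpr))
        assert pts == [(0, 0), (0, 0.5), (0, 1), (0.5, 1), (1, 1)]

    def test_endpoints_and_monotonicity(self, rng):
        curve = roc_curve(rng.standard_normal(40), rng.standard_normal(40) + 0.5)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)


class TestPowerHarness:
    def test_null_vs_null_power_matches_size(self):
        table = power_ma_models(
            [1], p=10, n1=20, n2=20, theta_alt=0.5, reps=200, seed=8
        )
        linear = table[(table.method == "linear") & (table["size"] == 0.05)]
        # alt == null here, so power estimates the size itself
        assert abs(float(linear.power.iloc[0]) - 0.05) < 0.05

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError, match="50"):
            power_ma_models([1], reps=10)

    def test_power_comparison_dispatches_on_spec_type(self):
        from netcov.simulate import power_comparison

        ma = power_comparison(
            [MAModelSpec(model=1, p=6, n=12, theta=0.2)], reps=60, seed=4
        )
        assert set(ma.method) == {"linear", "rbf:1", "rbf:10"}
        cov = power_comparison(
            [CovModelSpec(model=1, p=10, n_per_class=12)], reps=60, seed=4
        )
        assert set(cov.method) == {"chen", "cai"}
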