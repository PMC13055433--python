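import numpy as np
import pytest

from cosmoda import (ModelParams, ScenarioSpec, banded_interaction_matrix,
                     da_base_params, make_da_scenario, make_recovery_benchmark,
                     sample_power_interaction, tile_block_diagonal)
from cosmoda.power_model import unnorm_logdensity


class TestBandedMatrix:
    def test_printed_small_example(self):
        K = banded_interaction_matrix(4, 1)
        assert K[0, 1] == pytest.approx(-0.5)   # 1/2 - 1
        np.testing.assert_allclose(np.diag(K), [0.5, 1.0, 1.0, 0.5])

    @pytest.mark.parametrize("p,s", [(10, 1), (50, 3), (100, 2), (100, 7)])
    def test_zero_row_sums_symmetric_psd(self, p, s):
        K = banded_interaction_matrix(p, s)
        np.testing.assert_array_equal(K, K.T)
        np.testing.assert_allclose(K.sum(axis=1), 0.0, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-12

    def test_band_structure(self):
        K = banded_interaction_matrix(8, 2)
        assert K[0, 3] == 0.0
        assert K[0, 2] == pytest.approx(2 / 3 - 1)

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            banded_interaction_matrix(5, 5)

    def test_block_diagonal_tiling_preserves_row_sums(self):
        K, _ = da_base_params()
        big = tile_block_diagonal(K, 9)
        assert big.shape == (99, 99)
        np.testing.assert_allclose(big.sum(axis=1), 0.0, atol=1e-12)
        np.testing.assert_array_equal(big[:11, :11], K)
        assert np.all(big[:11, 11:] == 0.0)


class TestSampler:
    def test_rows_on_simplex(self):
        p = 6
        params = ModelParams(0.0, 0.0, banded_interaction_matrix(p, 2), -np.ones(p))
        X = sample_power_interaction(50, params, seed=1, burn_in=200, thin=2)
        assert X.shape == (50, p)
        np.testing.assert_allclose(X.sum(axis=1), 1.0, atol=1e-10)
        assert X.min() >= 0

    def test_dirichlet_oracle_moments(self):
        """With K = 0, a=b=0, eta = alpha-1 the model is Dirichlet(alpha)."""
        alpha = np.array([2.0, 3.0, 4.0])
        params = ModelParams(0.0, 0.0, np.zeros((3, 3)), alpha - 1.0)
        X = sample_power_interaction(5000, params, seed=3, burn_in=500, thin=2,
                                     chains="single")
        means = X.mean(axis=0)
        se = X.std(axis=0) / np.sqrt(X.shape[0])
        np.testing.assert_array_less(np.abs(means - alpha / alpha.sum()), 3 * se + 1e-4)

    def test_seed_determinism(self):
        p = 4
        params = ModelParams(0.0, 0.0, banded_interaction_matrix(p, 1), -np.ones(p))
        X1 = sample_power_interaction(10, params, seed=5, burn_in=100, thin=2)
        X2 = sample_power_interaction(10, params, seed=5, burn_in=100, thin=2)
        np.testing.assert_array_equal(X1, X2)
        X3 = sample_power_interaction(10, params, seed=6, burn_in=100, thin=2)
        assert np.abs(X1 - X3).max() > 0

    def test_improper_model_rejected(self):
        p = 3
        params = ModelParams(0.0, 0.0, np.zeros((p, p)), np.array([-2.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="improper"):
            sample_power_interaction(5, params, seed=0)

    def test_pair_histogram_matches_quadrature(self):
        """Long-chain 2-D histogram vs direct integration of the density."""
        K = np.array([[1.0, -0.6, -0.4], [-0.6, 1.1, -0.5], [-0.4, -0.5, 0.9]])
        eta = np.array([0.5, -0.3, 0.2])
        params = ModelParams(1.0, 1.0, K, eta)
        X = sample_power_interaction(20000, params, seed=11, burn_in=500, thin=2,
                                     chains="single")
        G, F = 20, 400
        fe = np.linspace(0, 1, F + 1)
        fm = (fe[:-1] + fe[1:]) / 2
        x1, x2 = np.meshgrid(fm, fm, indexing="ij")
        x3 = 1 - x1 - x2
        mask = x3 > 0
        Z = np.stack([x1 - 1, x2 - 1, np.where(mask, x3, 1) - 1], axis=-1)
        q = -0.5 * np.einsum("...i,ij,...j->...", Z, K, Z) + Z @ eta
        dens = np.where(mask, np.exp(q), 0.0)
        fac = F // G
        P = dens.reshape(G, fac, G, fac).sum(axis=(1, 3))
        P /= P.sum()
        H, _, _ = np.histogram2d(X[:, 0], X[:, 1], bins=[np.linspace(0, 1, G + 1)] * 2)
        H /= H.sum()
        assert 0.5 * np.abs(H - P).sum() < 0.05

    def test_effect_sign_shows_in_group_means(self):
        """Positive tau on eta0<0 makes the location more negative: the
        targeted feature should shrink in the case group."""
        K, eta0 = da_base_params()
        spec = ScenarioSpec(p=11, n=2000, tau=1.0, target_features=(0,),
                            base_K=K, base_eta0=eta0, seed=4,
                            mcmc=dict(burn_in=400, thin=2, chains="single"))
        ds, truth = make_da_scenario(spec)
        diff = ds.X[ds.y == 1, 0].mean() - ds.X[ds.y == 0, 0].mean()
        assert truth[0] and diff < 0


class TestScenarios:
    def test_effect_vector_construction(self):
        K, eta0 = da_base_params()
        spec = ScenarioSpec(p=11, n=10, tau=0.5, target_features=(0, 6),
                            base_K=K, base_eta0=eta0)
        eta1 = spec.eta1
        np.testing.assert_allclose(eta1[[0, 6]], 0.5 * eta0[[0, 6]])
        assert np.all(eta1[[1, 2, 3, 4, 5, 7, 8, 9, 10]] == 0.0)
        np.testing.assert_array_equal(spec.truth, eta1 != 0)

    def test_null_scenario_has_no_truth(self):
        K, eta0 = da_base_params()
        spec = ScenarioSpec(p=11, n=8, tau=0.0, target_features=(0,),
                            base_K=K, base_eta0=eta0)
        assert not spec.truth.any()

    def test_equal_split_enforced(self):
        K, eta0 = da_base_params()
        with pytest.raises(ValueError, match="even"):
            ScenarioSpec(p=11, n=9, tau=0.5, target_features=(0,),
                         base_K=K, base_eta0=eta0)

    def test_recovery_benchmark_reproducible(self):
        d1, K1 = make_recovery_benchmark(p=8, n=6, s=2, R=1, seed=3,
                                         burn_in=50, thin=1)
        d2, K2 = make_recovery_benchmark(p=8, n=6, s=2, R=1, seed=3,
                                         burn_in=50, thin=1)
        np.testing.assert_array_equal(d1[0].X, d2[0].X)
        np.testing.assert_array_equal(K1, K2)

    def test_recovery_benchmark_misspecified_covariate(self):
        ds, _ = make_recovery_benchmark(p=6, n=10, s=1, R=1, seed=2,
                                        covariate=True, burn_in=50, thin=1)
        assert set(np.unique(ds[0].y)) <= {0.0, 1.0}
        assert np.ptp(ds[0].y) == 1.0
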