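import numpy as np
import pytest

from cosmoda import (CompositionDataset, ModelParams, WeightSpec,
                     build_score_system, default_delta, log_density_partials,
                     loss_direct, unnorm_logdensity, weight_function)


class TestWeightFunction:
    @pytest.mark.parametrize("x, j, expected", [
        (np.array([0.5, 0.5]), 0, 0.25),          # x_j = x_p = 0.5
        (np.array([0.0, 0.5, 0.5]), 0, 0.0),      # boundary: weight vanishes
        (np.array([0.9, 0.05, 0.05]), 0, 0.0025),  # min picks x_p
    ])
    def test_default_weight_values(self, x, j, expected):
        assert weight_function(x, j) == pytest.approx(expected)

    def test_profiled_coordinate_excluded(self):
        with pytest.raises(IndexError):
            weight_function(np.array([0.5, 0.5]), 1)


class TestPartials:
    def test_zero_params_zero_partials(self, rng):
        p = 4
        params = ModelParams(0.5, 0.5, np.zeros((p, p)), np.zeros(p))
        first, second = log_density_partials(rng.dirichlet(np.ones(p)), 1.0, params)
        np.testing.assert_array_equal(first, 0.0)
        np.testing.assert_array_equal(second, 0.0)

    def test_covariate_off_matches_plain_location(self, rng):
        p = 4
        K = rng.normal(size=(p, p))
        eta0, eta1 = rng.normal(size=p), rng.normal(size=p)
        x = rng.dirichlet(np.ones(p))
        with_cov = log_density_partials(x, 0.0, ModelParams(0.3, 0.6, K, eta0, eta1))
        plain = log_density_partials(x, 0.0, ModelParams(0.3, 0.6, K, eta0))
        np.testing.assert_allclose(with_cov[0], plain[0])
        np.testing.assert_allclose(with_cov[1], plain[1])

    @pytest.mark.parametrize("a,b", [(0.0, 0.0), (0.7, 0.4), (1.0, 1.0)])
    def test_first_partials_match_finite_differences(self, rng, a, b):
        p = 3
        K = rng.normal(size=(p, p))
        K = (K + K.T) / 2
        params = ModelParams(a, b, K, rng.normal(size=p), rng.normal(size=p))
        x = rng.dirichlet(np.ones(p) * 3)
        yv = 0.8
        first, _ = log_density_partials(x, yv, params)
        h = 1e-6
        for j in range(p - 1):
            def f(xj):
                xx = x.copy()
                xx[j] = xj
                xx[p - 1] = 1.0 - xx[: p - 1].sum()
                return unnorm_logdensity(xx, yv, params)
            fd = (f(x[j] + h) - f(x[j] - h)) / (2 * h)
            assert first[j] == pytest.approx(fd, abs=1e-5)


class TestScoreSystemConstruction:
    @pytest.mark.parametrize("a,b", [(0.0, 0.0), (0.6, 0.6), (0.8, 0.2)])
    def test_quadratic_form_matches_direct_loss(self, rng, a, b):
        """Central correctness property: 1/2 th'G th - g'th == brute-force loss."""
        n, p = 6, 4
        X = rng.dirichlet(np.ones(p) * 2, size=n)
        y = rng.normal(size=n)
        ds = CompositionDataset(X, y)
        system = build_score_system(ds, a, b)
        for _ in range(7):
            th = rng.normal(size=system.r)
            params = ModelParams.from_theta(th, p, a, b, symmetrize=False)
            direct = loss_direct(ds, params)
            quad = system.loss(th)
            assert quad == pytest.approx(direct, rel=1e-8, abs=1e-10)

    def test_gamma_symmetric_psd(self, small_dataset):
        system = build_score_system(small_dataset, 0.0, 0.0)
        G = system.Gamma
        assert np.abs(G - G.T).max() < 1e-8
        ev = np.linalg.eigvalsh(G)
        assert ev.min() >= -1e-8 * np.abs(ev).max()

    def test_per_sample_components_average_to_aggregate(self, small_dataset):
        system = build_score_system(small_dataset, 0.5, 0.5)
        Gs = np.zeros_like(system.Gamma)
        gs = np.zeros_like(system.g)
        for i in range(system.n):
            Gi, gi = system.per_sample(i)
            Gs += Gi
            gs += gi
        np.testing.assert_allclose(Gs / system.n, system.GammaDelta, atol=1e-10)
        np.testing.assert_allclose(gs / system.n, system.g, atol=1e-10)

    def test_covariate_block_identities_real_valued_y(self, rng):
        n, p = 15, 4
        X = rng.dirichlet(np.ones(p) * 2, size=n)
        y = rng.normal(size=n)
        full = build_score_system(CompositionDataset(X, y), 0.0, 0.0)
        p2 = p * p
        # per-sample eta0-block pieces weighted by y reproduce the eta1 blocks
        per = [build_score_system(CompositionDataset(X[i:i + 1], np.zeros(1)),
                                  0.0, 0.0, covariate=True) for i in range(n)]
        G_eta0_i = np.array([s.Gamma[p2:p2 + p, p2:p2 + p] for s in per])
        GK_eta0_i = np.array([s.Gamma[:p2, p2:p2 + p] for s in per])
        g_eta0_i = np.array([s.g[p2:p2 + p] for s in per])
        np.testing.assert_allclose(full.Gamma[:p2, p2 + p:],
                                   np.einsum("i,ijk->jk", y, GK_eta0_i) / n, atol=1e-10)
        np.testing.assert_allclose(full.Gamma[p2:p2 + p, p2 + p:],
                                   np.einsum("i,ijk->jk", y, G_eta0_i) / n, atol=1e-10)
        np.testing.assert_allclose(full.Gamma[p2 + p:, p2 + p:],
                                   np.einsum("i,ijk->jk", y ** 2, G_eta0_i) / n, atol=1e-10)
        np.testing.assert_allclose(full.g[p2 + p:], (y[:, None] * g_eta0_i).mean(0),
                                   atol=1e-12)

    def test_constant_unit_covariate_duplicates_eta0_blocks(self, rng):
        n, p = 10, 4
        X = rng.dirichlet(np.ones(p), size=n)
        system = build_score_system(CompositionDataset(X, np.ones(n)), 0.0, 0.0,
                                    covariate=True)
        p2 = p * p
        np.testing.assert_allclose(system.Gamma[p2 + p:, p2 + p:],
                                   system.Gamma[p2:p2 + p, p2:p2 + p])
        np.testing.assert_allclose(system.g[p2 + p:], system.g[p2:p2 + p])

    def test_sample_permutation_invariance(self, rng, small_dataset):
        system = build_score_system(small_dataset, 0.3, 0.3)
        perm = rng.permutation(small_dataset.n)
        shuffled = CompositionDataset(small_dataset.X[perm], small_dataset.y[perm])
        system2 = build_score_system(shuffled, 0.3, 0.3)
        np.testing.assert_allclose(system.Gamma, system2.Gamma, atol=1e-12)
        np.testing.assert_allclose(system.g, system2.g, atol=1e-12)

    def test_duplicating_samples_preserves_loss(self, rng, small_dataset):
        params = ModelParams.from_theta(rng.normal(size=24), 4, 0.5, 0.5,
                                        symmetrize=False)
        doubled = CompositionDataset(np.vstack([small_dataset.X] * 2),
                                     np.concatenate([small_dataset.y] * 2))
        assert loss_direct(doubled, params) == pytest.approx(
            loss_direct(small_dataset, params), rel=1e-12)

    def test_delta_scaling_touches_only_k_diagonal(self, small_dataset):
        system = build_score_system(small_dataset, 0.0, 0.0)
        diff = system.GammaDelta - system.Gamma
        off = diff.copy()
        kk = system.k_diag_index
        off[kk, kk] = 0.0
        assert np.abs(off).max() == 0.0
        assert np.all(diff[kk, kk] >= 0)

    def test_zeros_with_log_power_rejected(self, rng):
        X = rng.dirichlet(np.ones(4), size=5)
        X[0, 1] = 0.0
        X[0] /= X[0].sum()
        with pytest.raises(ValueError, match="pseudocount"):
            build_score_system(CompositionDataset(X, None), 0.0, 0.0)

    def test_zeros_tolerated_for_positive_powers(self, rng):
        X = rng.dirichlet(np.ones(4), size=8)
        X[0, 1] = 0.0
        X[0] /= X[0].sum()
        system = build_score_system(CompositionDataset(X, None), 0.5, 0.5)
        assert np.all(np.isfinite(system.Gamma))

    def test_memory_guard(self, rng):
        X = rng.dirichlet(np.ones(200), size=3)
        with pytest.raises(MemoryError, match="filter features"):
            build_score_system(CompositionDataset(X, None), 0.0, 0.0)


def test_default_delta_exceeds_one():
    for n, p in [(80, 100), (1000, 100), (50, 5)]:
        assert 1.0 < default_delta(n, p) < 2.0


def test_truncation_constant_caps_weight():
    spec = WeightSpec(c=1.0, Cj=0.1)
    assert weight_function(np.array([0.45, 0.3, 0.25]), 0, spec) == pytest.approx(0.1)
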