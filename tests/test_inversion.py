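import numpy as np
import pytest

import mdinvert as mi
from mdinvert.inversion import mutate_mc, proliferate
from mdinvert.signal_model import ComponentBounds, default_bounds


class TestNnls:
    def test_identity_system(self):
        w, r = mi.nnls_fit(np.eye(2), np.array([0.3, 0.7]))
        assert np.allclose(w, [0.3, 0.7], atol=1e-12)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_scaled_single_column(self):
        rng = np.random.default_rng(0)
        K = rng.random((12, 4))
        s = 0.8 * K[:, 2]
        w, r = mi.nnls_fit(K, s)
        assert w[2] == pytest.approx(0.8, abs=1e-8)
        assert r == pytest.approx(0.0, abs=1e-8)

    def test_exact_recovery_and_scipy_agreement(self):
        from scipy.optimize import nnls as scipy_nnls
        rng = np.random.default_rng(1)
        for _ in range(20):
            K = rng.random((10, 3)) + 0.1
            w_true = rng.random(3)
            s = K @ w_true
            w, r = mi.nnls_fit(K, s)
            assert np.allclose(w, w_true, atol=1e-8)
            w_ref, r_ref = scipy_nnls(K, s)
            assert np.allclose(w, w_ref, atol=1e-8)
            assert r == pytest.approx(r_ref, abs=1e-8)

    def test_wide_system_matches_scipy(self):
        from scipy.optimize import nnls as scipy_nnls
        rng = np.random.default_rng(2)
        K = rng.random((30, 300))
        s = K @ np.maximum(rng.random(300) - 0.97, 0)
        w, r = mi.nnls_fit(K, s)
        _, r_ref = scipy_nnls(K, s)
        assert r == pytest.approx(r_ref, abs=1e-8)

    def test_warm_start_reaches_same_optimum(self):
        rng = np.random.default_rng(3)
        K = rng.random((20, 40))
        s = K @ np.maximum(rng.random(40) - 0.9, 0)
        w_cold, r_cold = mi.nnls_fit(K, s)
        w_warm, r_warm = mi.nnls_fit(K, s, warm_start=np.arange(10))
        assert r_warm == pytest.approx(r_cold, abs=1e-10)
        assert np.allclose(w_warm, w_cold, atol=1e-8)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mi.nnls_fit(np.ones((3, 2)), np.ones(4))


class TestBootstrapPlan:
    def test_deterministic_given_seed(self):
        p1 = mi.draw_bootstrap_plan(5, 3, seed=9)
        p2 = mi.draw_bootstrap_plan(5, 3, seed=9)
        assert p1 == p2
        assert p1.indices.shape == (3, 5)

    def test_indices_in_range(self):
        p = mi.draw_bootstrap_plan(17, 50, seed=1)
        assert p.indices.min() >= 0 and p.indices.max() < 17

    def test_uniform_selection_frequency(self):
        # binomial check: each index selected with probability 1/M
        M, Nb = 139, 10_000 // 139 + 1
        p = mi.draw_bootstrap_plan(M, 80, seed=4)
        counts = np.bincount(p.indices.ravel(), minlength=M)
        n = p.indices.size
        se = np.sqrt(n * (1 / M) * (1 - 1 / M))
        assert np.all(np.abs(counts - n / M) < 4 * se + 1)


class TestSampling:
    def test_within_bounds(self):
        b = default_bounds()
        rng = np.random.default_rng(0)
        comps = mi.sample_components(b, 500, rng)
        assert np.all(b.contains(comps))

    def test_degenerate_bounds_collapse(self):
        val = np.array([1.0, 0.5, 0.3, 0.4, 2.0, 100.0, 200.0, 1.0, 10.0])
        b = ComponentBounds(val, val)
        rng = np.random.default_rng(0)
        comps = mi.sample_components(b, 10, rng)
        assert np.allclose(comps, val)

    def test_orientation_uniform_on_sphere(self):
        b = default_bounds()
        rng = np.random.default_rng(5)
        comps = mi.sample_components(b, 100_000, rng)
        # cos(theta) uniform in [-1, 1] -> mean 0 with se = 1/sqrt(3n)
        mean_cos = np.cos(comps[:, 2]).mean()
        assert abs(mean_cos) < 4 / np.sqrt(3 * 100_000)


class TestProliferationMutation:
    def test_single_component_recovery(self, small_protocol):
        comp = np.array([[1.5, 0.4, 0.7, 1.0, 2.0, 150.0, 300.0, 1.2, 12.0]])
        s = mi.kernel_matrix(small_protocol, comp)[:, 0] * 0.9
        cfg = mi.McConfig(np_rounds=30, nm_rounds=10, nb=1, seed=0)
        rng = np.random.default_rng(0)
        row = np.arange(small_protocol.M)
        sol = proliferate(s, small_protocol, row, cfg, rng)
        sim = mi.signal_similarity(sol.fitted_signal, s)
        assert sim >= 0.999
        assert sol.n_components <= cfg.nc_max

    def test_component_cap_respected(self, small_signal, small_protocol,
                                     small_plan, fast_mc_config):
        sols = mi.mc_invert_voxel(small_signal, small_protocol, small_plan,
                                  fast_mc_config)
        assert len(sols) == small_plan.nb
        assert all(s.n_components <= fast_mc_config.nc_max for s in sols)
        assert all(np.all(s.weights > 0) for s in sols)

    def test_mutation_never_degrades_the_fit(self, small_signal,
                                             small_protocol, small_plan,
                                             fast_mc_config):
        rng = np.random.default_rng(2)
        row = small_plan.indices[0]
        sol_p = proliferate(small_signal, small_protocol, row,
                            fast_mc_config, rng)
        sol_m = mutate_mc(sol_p, small_signal, small_protocol, row,
                          fast_mc_config, rng)
        assert sol_m.residual_norm <= sol_p.residual_norm + 1e-12

    def test_zero_perturbation_scale_is_identity(self, small_signal,
                                                 small_protocol, small_plan):
        from mdinvert.perturb import SigmaScheme
        cfg = mi.McConfig(np_rounds=4, nm_rounds=3, nb=1, seed=1,
                          sigma_scheme=SigmaScheme(0.0, 0.0))
        rng = np.random.default_rng(3)
        row = small_plan.indices[1]
        sol_p = proliferate(small_signal, small_protocol, row, cfg, rng)
        sol_m = mutate_mc(sol_p, small_signal, small_protocol, row, cfg, rng)
        assert np.array_equal(sol_m.components, sol_p.components)
        assert sol_m.residual_norm == pytest.approx(sol_p.residual_norm,
                                                    abs=1e-12)

    def test_all_zero_signal_gives_empty_solution(self, small_protocol,
                                                  fast_mc_config):
        rng = np.random.default_rng(0)
        sol = proliferate(np.zeros(small_protocol.M), small_protocol,
                          np.arange(small_protocol.M), fast_mc_config, rng)
        assert sol.is_empty

    def test_voxel_inversion_is_deterministic(self, small_signal,
                                              small_protocol, small_plan,
                                              fast_mc_config):
        s1 = mi.mc_invert_voxel(small_signal, small_protocol, small_plan,
                                fast_mc_config)
        s2 = mi.mc_invert_voxel(small_signal, small_protocol, small_plan,
                                fast_mc_config)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.components, b.components)
            assert np.array_equal(a.weights, b.weights)
            assert a.residual_norm == b.residual_norm
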