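import numpy as np
import pytest

from crydx.adaptation import (
    AdaptationConfig,
    adapt,
    adapt_bml,
    adapt_coupled,
    adapt_map,
    bml_update_component,
    component_responsibilities,
    effective_counts,
)
from crydx.gmm_core import GMMParams
from crydx.synthetic_fixtures import sample_gmm
from conftest import random_gmm


def brute_posteriors(X, g):
    """Independent posterior computation in the linear domain."""
    dens = np.zeros((X.shape[0], g.K))
    for i in range(g.K):
        dens[:, i] = g.weights[i] * np.prod(
            np.exp(-0.5 * (X - g.means[i]) ** 2 / g.variances[i])
            / np.sqrt(2 * np.pi * g.variances[i]),
            axis=1,
        )
    return dens / dens.sum(axis=1, keepdims=True)


class TestResponsibilities:
    def test_single_component_degeneracy(self, rng):
        g = random_gmm(1, 3, seed=0)
        X = rng.standard_normal((10, 3))
        r = component_responsibilities(X, g, 0)
        assert np.allclose(r.w, 1.0)
        assert np.allclose(r.gamma, 0.1)
        assert r.n_k == pytest.approx(10.0)

    def test_dominant_component_at_far_mean(self):
        g = GMMParams(
            weights=[0.5, 0.5],
            means=[[0.0, 0.0], [50.0, 50.0]],
            variances=[[1.0, 1.0], [1.0, 1.0]],
        )
        X = np.array([[50.0, 50.0]])
        r = component_responsibilities(X, g, 1)
        assert g.weights[1] * r.w[0] == pytest.approx(1.0, abs=1e-6)

    def test_scaled_weight_equals_brute_force_posterior(self, rng):
        g = random_gmm(4, 3, seed=3, spread=2.0)
        X = rng.standard_normal((30, 3)) * 2
        post = brute_posteriors(X, g)
        for k in range(4):
            r = component_responsibilities(X, g, k)
            assert np.allclose(g.weights[k] * r.w, post[:, k], atol=1e-10)

    def test_out_of_range_component_rejected(self, rng):
        with pytest.raises(IndexError):
            component_responsibilities(rng.standard_normal((5, 2)), random_gmm(2, 2, seed=0), 5)


class TestBmlComponentUpdate:
    def test_k1_single_iteration_gives_sample_moments(self, rng):
        g = random_gmm(1, 3, seed=1)
        X = rng.standard_normal((200, 3)) * 1.5 + 0.3
        out = bml_update_component(g, X, 0, iters=1)
        assert np.allclose(out.means[0], X.mean(axis=0), atol=1e-10)
        assert np.allclose(out.variances[0], X.var(axis=0), atol=1e-10)
        assert out.weights[0] == pytest.approx(1.0)

    def test_isolated_component_adapts_others_untouched(self):
        g = GMMParams(
            weights=[0.5, 0.5],
            means=[[0.0], [40.0]],
            variances=[[1.0], [1.0]],
        )
        r = np.random.default_rng(0)
        X = r.standard_normal((50000, 1)) + 40.5  # from component 1, shifted
        out = bml_update_component(g, X, 1, iters=2)
        assert abs(out.means[1, 0] - 40.5) < 0.05
        assert np.array_equal(out.means[0], g.means[0])
        assert np.array_equal(out.variances[0], g.variances[0])

    def test_variance_flag_contract(self, rng):
        g = random_gmm(3, 2, seed=2)
        X = rng.standard_normal((100, 2))
        out = bml_update_component(g, X, 0, iters=2, update_variance=False)
        assert np.array_equal(out.variances, g.variances)


class TestAdaptBml:
    def test_self_consistency_on_ubm_samples(self):
        g = random_gmm(4, 5, seed=7, spread=6.0)
        X = sample_gmm(g, 100_000, seed=1).X
        out = adapt_bml(g, X, AdaptationConfig(method=2))
        sd = np.sqrt(g.variances)
        assert np.all(np.abs(out.means - g.means) < 0.05 * sd + 0.05)

    def test_method4_leaves_weights_and_variances_exact(self, rng):
        g = random_gmm(3, 4, seed=8)
        X = sample_gmm(g, 5000, seed=2).X
        out = adapt_bml(g, X, AdaptationConfig(method=4))
        assert np.array_equal(out.weights, g.weights)
        assert np.array_equal(out.variances, g.variances)
        assert not np.array_equal(out.means, g.means)

    def test_recovers_mean_shift_direction(self):
        g = random_gmm(4, 5, seed=9, spread=6.0)
        delta = 0.8 * np.sqrt(g.variances)
        shifted = g.copy()
        shifted.means = shifted.means + delta
        X = sample_gmm(shifted, 50_000, seed=3).X
        out = adapt_bml(g, X, AdaptationConfig(method=2))
        displacement = out.means - g.means
        # each well-populated component moves more than halfway toward +delta
        proj = np.sum(displacement * delta, axis=1) / np.sum(delta * delta, axis=1)
        assert np.all(proj > 0.5)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            adapt_bml(random_gmm(2, 2, seed=0), np.empty((0, 2)), AdaptationConfig(method=2))


class TestAdaptMap:
    def test_zero_mass_component_unchanged(self):
        g = GMMParams(
            weights=[0.5, 0.5],
            means=[[0.0], [1000.0]],
            variances=[[1.0], [1.0]],
        )
        r = np.random.default_rng(1)
        X = r.standard_normal((500, 1))  # all mass on component 0
        out = adapt_map(g, X, r=16.0)
        assert np.array_equal(out.means[1], g.means[1])

    def test_n_equals_r_gives_exact_midpoint(self, rng):
        g = GMMParams(weights=[1.0], means=[[2.0, -1.0]], variances=[[1.0, 1.0]])
        X = rng.standard_normal((16, 2)) + 5.0
        out = adapt_map(g, X, r=16.0)
        expected = 0.5 * X.mean(axis=0) + 0.5 * g.means[0]
        assert np.allclose(out.means[0], expected, atol=1e-12)

    def test_matches_textbook_reference_formula(self, rng):
        g = random_gmm(4, 3, seed=10, spread=2.0)
        X = rng.standard_normal((300, 3)) * 2
        out = adapt_map(g, X, r=16.0)
        post = brute_posteriors(X, g)
        n = post.sum(axis=0)
        E = (post.T @ X) / n[:, None]
        alpha = n / (n + 16.0)
        expected = alpha[:, None] * E + (1 - alpha[:, None]) * g.means
        assert np.allclose(out.means, expected, atol=1e-10)
        assert np.array_equal(out.variances, g.variances)
        assert np.array_equal(out.weights, g.weights)


class TestAdaptCoupled:
    def test_alpha_zero_limit_returns_ubm(self):
        g = GMMParams(
            weights=[0.5, 0.5],
            means=[[0.0], [1000.0]],
            variances=[[1.0], [1.0]],
        )
        r = np.random.default_rng(2)
        X = r.standard_normal((200, 1))
        out = adapt_coupled(g, X, AdaptationConfig(method=3))
        # component 1 has essentially zero mass -> stays at the UBM value
        assert np.allclose(out.means[1], g.means[1], atol=1e-6)

    def test_alpha_one_limit_approaches_pure_bml(self):
        g = random_gmm(2, 3, seed=11, spread=8.0)
        X = sample_gmm(g, 200_000, seed=4).X
        cfg = AdaptationConfig(method=3)
        coupled = adapt_coupled(g, X, cfg)
        bml = adapt_bml(g, X, AdaptationConfig(method=2))
        # n_i >> r so alpha ~ 1: coupled ~ BML
        assert np.allclose(coupled.means, bml.means, atol=1e-3)

    def test_single_component_midpoint_arithmetic(self, rng):
        g = GMMParams(weights=[1.0], means=[[0.0]], variances=[[4.0]])
        X = rng.standard_normal((16, 1)) + 3.0  # n = 16 = r -> alpha = 0.5
        out = adapt_coupled(g, X, AdaptationConfig(method=3, n_sweeps=1, per_component_iters=1))
        bml_mean = X.mean()
        assert out.means[0, 0] == pytest.approx(0.5 * bml_mean + 0.5 * 0.0, abs=1e-10)


class TestMethodInvariants:
    @pytest.mark.parametrize("method", [1, 2, 3, 4])
    def test_simplex_floor_and_shape_preserved(self, method, rng):
        g = random_gmm(4, 3, seed=12, spread=4.0)
        X = sample_gmm(g, 3000, seed=5).X
        out = adapt(g, X, AdaptationConfig(method=method))
        assert out.K == g.K and out.dim == g.dim
        assert out.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(out.weights >= 0)
        assert np.all(out.variances > 0)

    @pytest.mark.parametrize("method", [1, 4])
    def test_mean_only_methods_keep_variances_bit_identical(self, method, rng):
        g = random_gmm(4, 3, seed=13)
        X = sample_gmm(g, 2000, seed=6).X
        out = adapt(g, X, AdaptationConfig(method=method))
        assert np.array_equal(out.variances, g.variances)

    def test_effective_counts_sum_to_frame_count(self, rng):
        g = random_gmm(5, 3, seed=14)
        X = rng.standard_normal((400, 3))
        assert effective_counts(X, g).sum() == pytest.approx(400.0, abs=1e-8)
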