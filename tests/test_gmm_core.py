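import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from crydx.gmm_core import (
    EMConfig,
    GMMParams,
    avg_loglik,
    gmm_logpdf,
    pool_balanced,
    train_gmm_em,
    variance_floor,
)
from conftest import random_gmm


class TestLogpdf:
    def test_standard_normal_peak(self):
        g = GMMParams(weights=[1.0], means=[[0.0]], variances=[[1.0]])
        assert gmm_logpdf(np.array([0.0]), g) == pytest.approx(np.log(1 / np.sqrt(2 * np.pi)), abs=1e-9)

    def test_symmetric_two_component_midpoint(self):
        m = 2.0
        g = GMMParams(weights=[0.5, 0.5], means=[[m], [-m]], variances=[[1.0], [1.0]])
        expected = -0.5 * np.log(2 * np.pi) - 0.5 * m * m
        assert gmm_logpdf(np.array([0.0]), g) == pytest.approx(expected, abs=1e-9)

    def test_matches_linear_domain_oracle(self, rng):
        for trial in range(50):
            g = random_gmm(5, 3, seed=trial)
            x = rng.standard_normal(3) * 3
            linear = sum(
                g.weights[i]
                * np.prod(
                    np.exp(-0.5 * (x - g.means[i]) ** 2 / g.variances[i])
                    / np.sqrt(2 * np.pi * g.variances[i])
                )
                for i in range(5)
            )
            assert gmm_logpdf(x, g) == pytest.approx(np.log(linear), rel=1e-10)

    def test_agrees_with_sklearn_reference(self, rng):
        g = random_gmm(4, 6, seed=9)
        sk = GaussianMixture(n_components=4, covariance_type="diag")
        sk.weights_, sk.means_ = g.weights, g.means
        sk.covariances_ = g.variances
        sk.precisions_cholesky_ = 1.0 / np.sqrt(g.variances)
        X = rng.standard_normal((100, 6))
        assert np.allclose(gmm_logpdf(X, g), sk.score_samples(X), atol=1e-8)

    def test_dimension_mismatch_rejected(self):
        g = random_gmm(2, 3, seed=0)
        with pytest.raises(ValueError):
            gmm_logpdf(np.zeros((5, 4)), g)


class TestAvgLoglik:
    def test_single_frame_equals_logpdf(self, rng):
        g = random_gmm(3, 2, seed=1)
        x = rng.standard_normal((1, 2))
        assert avg_loglik(x, g) == pytest.approx(gmm_logpdf(x[0], g))

    def test_duration_invariance_under_duplication(self, rng):
        g = random_gmm(3, 2, seed=2)
        X = rng.standard_normal((20, 2))
        assert avg_loglik(X, g) == pytest.approx(avg_loglik(np.repeat(X, 2, axis=0), g), abs=1e-12)

    def test_matches_per_frame_mean(self, rng):
        g = random_gmm(3, 2, seed=3)
        X = rng.standard_normal((50, 2))
        oracle = np.mean([gmm_logpdf(x, g) for x in X])
        assert avg_loglik(X, g) == pytest.approx(oracle, abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            avg_loglik(np.empty((0, 2)), random_gmm(2, 2, seed=0))


class TestEmTraining:
    def test_k1_closed_form_moments(self, rng):
        X = rng.standard_normal((500, 4)) * 2.0 + 1.0
        g = train_gmm_em(X, EMConfig(n_components=1, max_iters=1, seed=0))
        assert np.allclose(g.means[0], X.mean(axis=0), atol=1e-10)
        assert np.allclose(g.variances[0], X.var(axis=0), atol=1e-10)
        assert g.weights[0] == pytest.approx(1.0, abs=1e-12)

    def test_recovers_separated_three_component_mixture(self):
        r = np.random.default_rng(42)
        truth = np.array([[0.0, 0.0], [8.0, 8.0], [-8.0, 8.0]])
        comp = r.integers(0, 3, size=20000)
        X = truth[comp] + r.standard_normal((20000, 2))
        g = train_gmm_em(X, EMConfig(n_components=3, seed=0))
        # optimal matching of recovered to generating means
        for mu in truth:
            d = np.min(np.linalg.norm(g.means - mu, axis=1))
            assert d < 0.1

    def test_loglik_history_nondecreasing(self, rng):
        X = rng.standard_normal((2000, 3))
        g = train_gmm_em(X, EMConfig(n_components=4, seed=1))
        h = np.asarray(g.loglik_history)
        assert np.all(np.diff(h) >= -1e-8)

    def test_fixed_seed_bit_reproducible(self, rng):
        X = rng.standard_normal((1000, 3))
        a = train_gmm_em(X, EMConfig(n_components=4, seed=5))
        b = train_gmm_em(X, EMConfig(n_components=4, seed=5))
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.variances, b.variances)

    def test_weights_simplex_and_variance_floor(self, rng):
        X = rng.standard_normal((3000, 3))
        cfg = EMConfig(n_components=6, seed=2)
        g = train_gmm_em(X, cfg)
        assert g.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(g.weights >= 0)
        assert np.all(g.variances >= variance_floor(X, cfg.variance_floor_factor) - 1e-15)

    def test_more_components_than_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            train_gmm_em(rng.standard_normal((5, 2)), EMConfig(n_components=10))


class TestPoolBalanced:
    def test_health_independent_balancing_arithmetic(self, rng):
        frames = {
            "Healthy": rng.standard_normal((10000, 3)),
            "A": rng.standard_normal((2000, 3)),
            "B": rng.standard_normal((3000, 3)),
        }
        pooled = pool_balanced(frames, mode="health_independent", seed=0)
        assert pooled.shape == (10000, 3)  # 5000 healthy + 2500 + 2500

    def test_equal_classes_keep_every_frame(self, rng):
        frames = {"A": rng.standard_normal((100, 2)), "B": rng.standard_normal((100, 2))}
        pooled = pool_balanced(frames, mode="pathology_independent", seed=0)
        assert pooled.shape == (200, 2)
        # output is a permutation (here: concatenation) of the input frames
        allrows = np.vstack([frames["A"], frames["B"]])
        assert np.allclose(np.sort(pooled, axis=0), np.sort(allrows, axis=0))

    def test_single_pathology_class_rejected(self, rng):
        with pytest.raises(ValueError):
            pool_balanced({"A": rng.standard_normal((10, 2))}, mode="pathology_independent")

    def test_zero_frame_class_named_in_error(self, rng):
        frames = {"Healthy": rng.standard_normal((10, 2)), "Blood": np.empty((0, 2))}
        with pytest.raises(ValueError, match="Blood"):
            pool_balanced(frames, mode="health_independent")


class TestModelIO:
    def test_json_round_trip_preserves_parameters(self, tmp_path):
        g = random_gmm(3, 4, seed=11)
        g.tag = "HI-UBM-EXP"
        g.save(tmp_path / "m.json")
        back = GMMParams.load(tmp_path / "m.json")
        assert back.tag == "HI-UBM-EXP"
        assert np.allclose(back.means, g.means)
        assert np.allclose(back.weights, g.weights)

    def test_invalid_weights_rejected_on_load(self, tmp_path):
        import json

        d = random_gmm(2, 2, seed=0).to_dict()
        d["weights"] = [0.9, 0.6]
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(d))
        with pytest.raises(ValueError):
            GMMParams.load(p)
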