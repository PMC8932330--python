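"""Particle-swarm optimizer contracts: constraints, convergence, determinism."""

import numpy as np
import pytest

from fatiguefuse.ipso_svm import (
    FusionCoefficients,
    IpsoSvmClassifier,
    SwarmConfig,
    fit_ipso_svm,
    fitness,
    study_swarm_config,
    project_coefficients,
    pso_optimize,
)


def known_optimum_landscape(seed=3):
    rng = np.random.default_rng(seed)
    d_star = project_coefficients(np.abs(rng.normal(1.0, 0.5, 11)))
    return d_star, lambda d: 1.0 - np.linalg.norm(d - d_star) / np.linalg.norm(d_star)


class TestProjection:
    def test_projection_restores_sum_and_nonnegativity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = project_coefficients(rng.normal(0, 2, 11))
            assert p.sum() == pytest.approx(11.0, abs=1e-9)
            assert np.all(p >= 0)

    def test_all_zero_input_maps_to_uniform(self):
        np.testing.assert_array_equal(
            project_coefficients(np.zeros(3)), np.ones(3))

    def test_negative_components_mirrored(self):
        p = project_coefficients(np.array([-1.0, 2.0, 0.0]))
        np.testing.assert_allclose(p, np.array([1.0, 2.0, 0.0]))

    def test_invalid_coefficients_rejected(self):
        with pytest.raises(ValueError):
            FusionCoefficients(np.ones(11) * 2)
        with pytest.raises(ValueError):
            FusionCoefficients(np.array([12.0, -1.0] + [0.0] * 9))


class TestPsoOptimize:
    def test_recovers_known_optimum(self):
        d_star, landscape = known_optimum_landscape()
        best, history = pso_optimize(
            landscape, SwarmConfig(q=50, max_iter=200, h_e=1.0, seed=1))
        rel_err = np.linalg.norm(best.d - d_star) / np.linalg.norm(d_star)
        assert rel_err < 0.05
        assert len(history) <= 201

    def test_global_best_trace_non_decreasing(self):
        _, landscape = known_optimum_landscape(seed=5)
        _, history = pso_optimize(
            landscape, SwarmConfig(q=20, max_iter=50, h_e=1.0, seed=2))
        assert np.all(np.diff(history) >= 0)

    def test_constraint_holds_for_every_evaluated_position(self):
        seen = []

        def instrumented(d):
            seen.append(d.copy())
            return float(np.sum(d * np.arange(11)) / 110)

        pso_optimize(instrumented, SwarmConfig(q=10, max_iter=20, h_e=1.0, seed=3))
        assert len(seen) == 10 * 21
        for d in seen:
            assert d.sum() == pytest.approx(11.0, abs=1e-9)
            assert np.all(d >= 0)

    def test_zero_expected_fitness_terminates_immediately(self):
        _, landscape = known_optimum_landscape()
        best, history = pso_optimize(
            landscape, SwarmConfig(q=10, max_iter=100, h_e=0.0, seed=4))
        assert len(history) == 1  # initial evaluation only
        assert best.d.sum() == pytest.approx(11.0, abs=1e-9)

    def test_fixed_seed_bit_identical_trajectory(self):
        _, landscape = known_optimum_landscape()
        cfg = SwarmConfig(q=15, max_iter=40, h_e=1.0, seed=9)
        best1, hist1 = pso_optimize(landscape, cfg)
        best2, hist2 = pso_optimize(landscape, cfg)
        np.testing.assert_array_equal(best1.d, best2.d)
        assert hist1 == hist2

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SwarmConfig(q=0)
        with pytest.raises(ValueError):
            SwarmConfig(h_e=1.5)
        with pytest.raises(ValueError):
            SwarmConfig(c1=-0.1)

    def test_paper_profile_settings(self):
        cfg = study_swarm_config(seed=1)
        assert (cfg.q, cfg.c1, cfg.c2, cfg.omega, cfg.h_e) == (2000, 0.5, 0.5, 0.8, 0.95)


@pytest.fixture(scope="module")
def blobs11():
    rng = np.random.default_rng(7)
    centers = rng.normal(0, 3, (3, 11))
    X = np.vstack([rng.normal(c, 0.5, (20, 11)) for c in centers])
    y = np.repeat([-1, 0, 1], 20)
    return X, y


class TestFitness:

    def test_memorization_on_separable_data(self, blobs11):
        X, y = blobs11
        d = FusionCoefficients.ones()
        assert fitness(d, X, y, X, y, C=1000.0) == 1.0

    def test_random_labels_near_chance(self, blobs11):
        X, _ = blobs11
        rng = np.random.default_rng(11)
        rates = []
        for _ in range(10):
            y = rng.permutation(np.repeat([-1, 0, 1], 20))
            y_eval = rng.permutation(np.repeat([-1, 0, 1], 20))
            rates.append(fitness(FusionCoefficients.ones(), X, y, X, y_eval))
        # 600 eval decisions: binomial 95% band around 1/3 is ±~0.04
        assert abs(np.mean(rates) - 1 / 3) < 0.08

    def test_identity_fusion_equals_direct_svm_rate(self, blobs11):
        X, y = blobs11
        from fatiguefuse.svm import train_ovo_svm

        rate_direct = float(np.mean(
            train_ovo_svm(X, y, C=10.0).predict(X) == y))
        assert fitness(FusionCoefficients.ones(), X, y, X, y) == rate_direct

    def test_empty_split_rejected(self, blobs11):
        X, y = blobs11
        with pytest.raises(ValueError):
            fitness(FusionCoefficients.ones(), X[:0], y[:0], X, y)


@pytest.fixture(scope="module")
def dataset():
    rng = np.random.default_rng(13)
    centers = rng.normal(0, 2.5, (3, 11))
    X = np.vstack([rng.normal(c, 1.2, (30, 11)) for c in centers])
    y = np.repeat([-1, 0, 1], 30)
    return X, y


class TestFitIpsoSvm:

    def test_missing_state_rejected(self, dataset):
        X, y = dataset
        mask = y != 0
        with pytest.raises(ValueError, match="0"):
            fit_ipso_svm(X[mask], y[mask])

    def test_same_seed_identical_model(self, dataset):
        X, y = dataset
        cfg = SwarmConfig(q=10, max_iter=5, h_e=1.0, seed=21)
        _, d1, r1 = fit_ipso_svm(X, y, cfg=cfg)
        _, d2, r2 = fit_ipso_svm(X, y, cfg=cfg)
        np.testing.assert_array_equal(d1.d, d2.d)
        assert r1["h_g_trace"] == r2["h_g_trace"]

    def test_report_contents(self, dataset):
        X, y = dataset
        cfg = SwarmConfig(q=8, max_iter=4, h_e=0.999, seed=2)
        clf, d, report = fit_ipso_svm(X, y, cfg=cfg)
        assert 0 <= report["final_h_g"] <= 1
        assert report["iterations"] <= 4
        assert d.d.sum() == pytest.approx(11.0, abs=1e-9)
        assert set(np.unique(clf.predict(X))) <= {-1, 0, 1}

    def test_serialization_roundtrip_preserves_predictions(self, dataset, tmp_path):
        X, y = dataset
        cfg = SwarmConfig(q=8, max_iter=3, h_e=1.0, seed=5)
        clf, _, _ = fit_ipso_svm(X, y, cfg=cfg)
        path = tmp_path / "model.json"
        clf.save(path)
        loaded = IpsoSvmClassifier.load(path)
        np.testing.assert_array_equal(clf.predict(X), loaded.predict(X))
        np.testing.assert_array_equal(clf.coefficients.d, loaded.coefficients.d)
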