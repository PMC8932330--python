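"""OVO RBF-SVM against an independent dual-QP reference solution."""

import json

import numpy as np
import pytest
from sklearn.svm import SVC

from fatiguefuse.ipso_svm import FusionCoefficients, IpsoSvmClassifier, fuse
from fatiguefuse.svm import PAIRS, BinarySvm, OvoSvmModel, train_ovo_svm

from qp_oracle import decision_values, solve_dual


def toy_sets():
    rng = np.random.default_rng(42)
    sep_x = np.array([[0.0, 0], [0, 1], [1, 0], [4, 4], [5, 4], [4, 5]])
    sep_y = np.array([-1, -1, -1, 1, 1, 1.0])
    xor_x = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
    xor_y = np.array([1, 1, -1, -1.0])
    ovl_x = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(1.0, 1, (10, 2))])
    ovl_y = np.repeat([-1.0, 1.0], 10)
    return [("separable", sep_x, sep_y, 100.0, 1.5),
            ("xor", xor_x, xor_y, 100.0, 0.8),
            ("overlap", ovl_x, ovl_y, 5.0, 1.5)]


class TestBinaryDualSolution:
    @pytest.mark.parametrize("name,X,y,C,sigma",
                             toy_sets(), ids=[t[0] for t in toy_sets()])
    def test_matches_reference_qp(self, name, X, y, C, sigma):
        """libsvm-trained sub-model ≡ SLSQP dual solution on ≤20 points."""
        svc = SVC(C=C, kernel="rbf", gamma=1.0 / sigma**2, tol=1e-6).fit(X, y)
        sub = BinarySvm(
            neg_label=-1, pos_label=1,
            support_vectors=svc.support_vectors_.copy(),
            dual_coef=svc.dual_coef_[0].copy(),
            bias=float(svc.intercept_[0]), C=C, sigma=sigma)
        alpha, bias = solve_dual(X, y, C, sigma)
        grid = np.vstack([X, X + 0.25])
        ref = decision_values(X, y, alpha, bias, grid, sigma)
        got = sub.decision_values(grid)
        np.testing.assert_allclose(got, ref, rtol=0, atol=1e-4)

    def test_separable_pair_perfect_training_accuracy(self):
        _, X, y, C, sigma = toy_sets()[0]
        svc = SVC(C=C, kernel="rbf", gamma=1.0 / sigma**2, tol=1e-6).fit(X, y)
        assert svc.score(X, y) == 1.0

    def test_xor_nonlinear_separability(self):
        _, X, y, C, sigma = toy_sets()[1]
        svc = SVC(C=C, kernel="rbf", gamma=1.0 / sigma**2, tol=1e-6).fit(X, y)
        assert svc.score(X, y) == 1.0

    def test_conflicting_duplicate_labels_soft_margin(self):
        X = np.array([[0.0, 0], [0, 0], [1, 1], [2, 2]])
        y = np.array([-1, 1, 1, -1])
        model = train_ovo_svm(
            np.vstack([X, [[5, 5]]]), np.array([-1, 1, 1, -1, 0]),
            C=1.0, sigma=1.0)
        assert model.fitted  # training completes despite the conflict


class TestOvoEnsemble:
    def test_three_sub_models_with_expected_pairs(self, blobs_3class):
        X, y = blobs_3class
        m = train_ovo_svm(X, y, C=10.0, sigma=1.5)
        assert [(s.neg_label, s.pos_label) for s in m.sub_models] == list(PAIRS)

    def test_dual_feasibility_every_sub_model(self, blobs_3class):
        X, y = blobs_3class
        m = train_ovo_svm(X, y, C=10.0, sigma=1.5)
        for sub in m.sub_models:
            box_violation, equality_residual = sub.dual_feasibility()
            assert box_violation <= 1e-9
            assert equality_residual <= 1e-6

    def test_missing_class_error_names_class(self):
        X = np.zeros((4, 2))
        y = np.array([-1, -1, 1, 1])
        with pytest.raises(ValueError, match="0"):
            train_ovo_svm(X, y)

    def test_deep_interior_point_classified_confidently(self, blobs_3class):
        X, y = blobs_3class
        m = train_ovo_svm(X, y, C=10.0, sigma=1.5)
        probe = np.array([[0.0, 3.0]])  # center of the class-1 blob
        assert m.predict(probe)[0] == 1
        # both sub-models involving class 1 put the probe on class 1's side
        for sub in m.sub_models:
            if sub.pos_label == 1:
                assert sub.decision_values(probe)[0] > 0

    def test_untrained_model_rejects_prediction(self):
        with pytest.raises(RuntimeError):
            OvoSvmModel().predict(np.zeros((1, 2)))

    def test_serialization_roundtrip_and_sv_order_invariance(self, blobs_3class):
        X, y = blobs_3class
        m = train_ovo_svm(X, y, C=10.0, sigma=1.5)
        m2 = OvoSvmModel.from_dict(json.loads(json.dumps(m.to_dict())))
        np.testing.assert_array_equal(m.predict(X), m2.predict(X))
        rng = np.random.default_rng(0)
        for sub in m2.sub_models:
            perm = rng.permutation(len(sub.dual_coef))
            sub.support_vectors = sub.support_vectors[perm]
            sub.dual_coef = sub.dual_coef[perm]
        np.testing.assert_array_equal(m.predict(X), m2.predict(X))


def _stub_sub(neg, pos, f_value):
    """A degenerate sub-model returning a fixed decision value everywhere."""
    return BinarySvm(neg_label=neg, pos_label=pos,
                     support_vectors=np.zeros((1, 2)),
                     dual_coef=np.array([0.0]), bias=f_value, C=1.0, sigma=1.0)


class TestVoteTieBreak:
    def test_cyclic_tie_broken_by_decision_strength(self):
        # genuine 1-1-1 vote tie: sub1 → -1, sub2 → 1, sub3 → 0
        m = OvoSvmModel(sub_models=[
            _stub_sub(-1, 0, -0.3),   # → -1, strength 0.3
            _stub_sub(-1, 1, +0.5),   # → 1, strength 0.5
            _stub_sub(0, 1, -0.9),    # → 0, strength 0.9
        ])
        assert m.predict(np.zeros((1, 2)))[0] == 0  # largest |f| wins

    def test_full_tie_falls_back_to_lowest_label(self):
        m = OvoSvmModel(sub_models=[
            _stub_sub(-1, 0, -0.5),   # → -1
            _stub_sub(-1, 1, +0.5),   # → 1
            _stub_sub(0, 1, -0.5),    # → 0
        ])
        assert m.predict(np.zeros((1, 2)))[0] == -1


class TestIdentityFusionEquivalence:
    def test_identity_weights_reproduce_plain_svm(self, blobs_3class):
        """d = 1 ⇒ the fused pipeline equals an unweighted multiclass SVM."""
        X, y = blobs_3class
        clf = IpsoSvmClassifier(optimize=False, C=10.0, sigma=1.5).fit(X, y)
        Xs = clf.scaler.transform(X)
        plain = SVC(C=10.0, kernel="rbf", gamma=1.0 / 1.5**2,
                    decision_function_shape="ovo").fit(Xs, y)
        rng = np.random.default_rng(1)
        probe = np.vstack([X, X + rng.normal(0, 0.2, X.shape)])
        np.testing.assert_array_equal(
            clf.predict(probe),
            plain.predict(clf.scaler.transform(probe)))

    def test_zero_weight_blanks_feature(self):
        d = np.ones(11)
        d[4] = 0.0
        d = d * (11 / d.sum())
        coeff = FusionCoefficients(d)
        x = np.arange(11, dtype=float)
        fused = fuse(x, coeff)
        assert fused[4] == 0.0

    def test_fuse_matches_elementwise_product(self):
        rng = np.random.default_rng(2)
        raw = np.abs(rng.normal(1, 0.3, 11))
        d = FusionCoefficients(raw * 11 / raw.sum())
        f = rng.normal(size=11)
        np.testing.assert_allclose(fuse(f, d), f * d.d, atol=1e-15)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.zeros(5), FusionCoefficients.ones(11))
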