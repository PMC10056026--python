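import math

import numpy as np
import pytest

from semgrej.classifier import (
    ClassCenters,
    ClassifierError,
    CnnArchitecture,
    CnnClassifier,
    TrainConfig,
    center_loss,
    center_loss_grad,
    joint_loss,
    softmax_cross_entropy,
    train_cnn,
    update_centers,
)
from semgrej.preprocessing import FeatureImage


class TestSoftmaxCrossEntropy:
    def test_uniform_logits(self):
        assert softmax_cross_entropy([[0.0, 0.0]], [0]) == pytest.approx(math.log(2))

    def test_worked_example(self):
        # -ln(e^2 / (e^2 + 2)) = ln(1 + 2 e^-2)
        assert softmax_cross_entropy([[2.0, 0.0, 0.0]], [0]) == pytest.approx(
            math.log(1 + 2 * math.exp(-2)), rel=1e-12
        )

    def test_confident_limit(self):
        assert softmax_cross_entropy([[60.0, 0.0, 0.0]], [0]) < 1e-20

    def test_label_out_of_range(self):
        with pytest.raises(ClassifierError, match="labels"):
            softmax_cross_entropy([[0.0, 0.0]], [2])

    def test_batch_mean(self, rng):
        logits = rng.standard_normal((8, 5))
        labels = rng.integers(0, 5, 8)
        singles = [softmax_cross_entropy(logits[i : i + 1], labels[i : i + 1]) for i in range(8)]
        assert softmax_cross_entropy(logits, labels) == pytest.approx(np.mean(singles), rel=1e-12)


class TestCenterLoss:
    def test_zero_at_centers(self, rng):
        c = ClassCenters(rng.standard_normal((3, 4)))
        labels = [0, 1, 2, 1]
        feats = c.centers[labels]
        assert center_loss(feats, labels, c) == 0.0

    def test_single_sample_half_squared_distance(self):
        c = ClassCenters(np.zeros((1, 4)))
        x = np.array([[1.0, 0.0, 0.0, 0.0]])
        assert center_loss(x, [0], c) == pytest.approx(0.5)

    def test_duplication_invariance(self, rng):
        c = ClassCenters(rng.standard_normal((3, 8)))
        feats = rng.standard_normal((5, 8))
        labels = [0, 1, 2, 0, 1]
        doubled = np.vstack([feats, feats])
        assert center_loss(doubled, labels * 2, c) == pytest.approx(
            center_loss(feats, labels, c), rel=1e-12
        )

    def test_non_negative(self, rng):
        c = ClassCenters(rng.standard_normal((4, 16)))
        feats = rng.standard_normal((20, 16))
        labels = rng.integers(0, 4, 20)
        assert center_loss(feats, labels, c) >= 0.0

    def test_gradient_matches_finite_differences(self, rng):
        for _ in range(5):
            c = ClassCenters(rng.standard_normal((3, 6)))
            feats = rng.standard_normal((7, 6))
            labels = rng.integers(0, 3, 7)
            analytic = center_loss_grad(feats, labels, c)
            eps = 1e-5
            for i in range(feats.shape[0]):
                for j in range(feats.shape[1]):
                    hi = feats.copy()
                    hi[i, j] += eps
                    lo = feats.copy()
                    lo[i, j] -= eps
                    num = (center_loss(hi, labels, c) - center_loss(lo, labels, c)) / (2 * eps)
                    assert analytic[i, j] == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestUpdateCenters:
    def test_worked_instance(self):
        c = ClassCenters(np.zeros((1, 2)), alpha=0.5)
        new = update_centers(c, np.array([[2.0, 2.0]]), [0])
        np.testing.assert_allclose(new.centers[0], [0.5, 0.5])

    def test_absent_class_unchanged(self, rng):
        c = ClassCenters(rng.standard_normal((3, 4)), alpha=0.5)
        new = update_centers(c, rng.standard_normal((2, 4)), [0, 0])
        np.testing.assert_array_equal(new.centers[1], c.centers[1])
        np.testing.assert_array_equal(new.centers[2], c.centers[2])

    def test_fixed_point_at_class_mean(self, rng):
        feats = rng.standard_normal((6, 4))
        mean = feats.mean(axis=0)
        c = ClassCenters(mean[None, :].copy(), alpha=0.5)
        new = update_centers(c, feats, [0] * 6)
        np.testing.assert_allclose(new.centers[0], mean, atol=1e-12)

    def test_iteration_converges_to_class_mean(self, rng):
        feats = rng.standard_normal((10, 8))
        labels = [0] * 6 + [1] * 4
        c = ClassCenters(np.zeros((2, 8)), alpha=0.5)
        for _ in range(200):
            c = update_centers(c, feats, labels)
        np.testing.assert_allclose(c.centers[0], feats[:6].mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(c.centers[1], feats[6:].mean(axis=0), atol=1e-6)

    def test_alpha_range_enforced(self):
        with pytest.raises(ClassifierError, match="alpha"):
            ClassCenters(np.zeros((1, 2)), alpha=1.0)


class TestJointLoss:
    def test_lambda_zero_reduces_to_cross_entropy(self, rng):
        logits = rng.standard_normal((6, 3))
        feats = rng.standard_normal((6, 8))
        labels = rng.integers(0, 3, 6)
        c = ClassCenters(rng.standard_normal((3, 8)))
        assert joint_loss(logits, feats, labels, c, 0.0) == softmax_cross_entropy(logits, labels)

    def test_features_at_centers(self, rng):
        logits = rng.standard_normal((4, 3))
        labels = np.array([0, 1, 2, 0])
        c = ClassCenters(rng.standard_normal((3, 8)))
        feats = c.centers[labels]
        assert joint_loss(logits, feats, labels, c, 0.5) == softmax_cross_entropy(logits, labels)

    def test_weighted_arithmetic(self):
        # CE = ln 2, CL = 0.5 with a unit-offset feature; lambda scales linearly
        logits = [[0.0, 0.0]]
        feats = np.array([[1.0, 0.0]])
        c = ClassCenters(np.zeros((2, 2)))
        lam = 0.00025
        expect = math.log(2) + lam * 0.5
        assert joint_loss(logits, feats, [0], c, lam) == pytest.approx(expect, rel=1e-12)


def _image(label, t=26, rng=None, scale=1.0):
    planes = (rng.random((3, t, 8)) if rng is not None else np.zeros((3, t, 8))) * scale
    return FeatureImage(planes=planes, label=label, kind="target", trial_id=0)


def small_dataset(seed=0, n_per_class=6, t=26, n_classes=3):
    """Linearly separable toy images: each class lights a distinct channel."""
    rng = np.random.default_rng(seed)
    images = []
    for k in range(n_classes):
        for _ in range(n_per_class):
            planes = rng.random((3, t, 8)) * 0.05
            planes[:, :, k] += 1.0
            images.append(FeatureImage(planes=planes, label=f"C{k}", kind="target", trial_id=0))
    return images


class TestCnnForward:
    def test_feature_dimension_and_simplex(self, rng):
        arch = CnnArchitecture(input_height=53, n_classes=7)
        model = CnnClassifier(arch, [f"C{i}" for i in range(7)], seed=0)
        out = model.forward(_image("C0", t=53, rng=rng))
        assert out.vector.shape == (512,)
        assert out.probabilities.shape == (7,)
        assert out.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(out.probabilities >= 0)

    def test_conv_stack_spatial_arithmetic(self):
        arch = CnnArchitecture(input_height=53)
        assert arch.conv_output_shape() == (64, 8, 4)

    def test_shape_mismatch_reports_both_shapes(self, rng):
        arch = CnnArchitecture(input_height=53, n_classes=3)
        model = CnnClassifier(arch, ["a", "b", "c"], seed=0)
        with pytest.raises(ClassifierError, match=r"\(3, 26, 8\).*\(3, 53, 8\)"):
            model.forward(_image("a", t=26, rng=rng))

    def test_inference_deterministic(self, rng):
        arch = CnnArchitecture(input_height=26, n_classes=3)
        model = CnnClassifier(arch, ["a", "b", "c"], seed=0)
        img = _image("a", rng=rng)
        f1 = model.forward(img)
        f2 = model.forward(img)
        np.testing.assert_array_equal(f1.vector, f2.vector)


@pytest.fixture(scope="module")
def trained():
    images = small_dataset()
    cfg = TrainConfig(epochs=40, seed=0)
    arch = CnnArchitecture(input_height=26, n_classes=3)
    return images, train_cnn(images, cfg, arch=arch)


class TestTraining:
    def test_history_length_and_learning(self, trained):
        images, (model, centers, history) = trained
        assert len(history) == 40
        assert history[-1].train_accuracy >= 0.95

    def test_feature_extraction_contracts(self, trained, rng):
        images, (model, centers, history) = trained
        feats = model.extract_features(images[:5])
        assert all(f.vector.shape == (512,) for f in feats)
        again = model.extract_features(images[:5])
        for a, b in zip(feats, again):
            np.testing.assert_array_equal(a.vector, b.vector)
        # permutation of the batch permutes outputs identically
        perm = model.extract_features(images[4::-1])
        for a, b in zip(perm, feats[::-1]):
            np.testing.assert_array_equal(a.vector, b.vector)

    def test_training_determinism(self):
        images = small_dataset()
        arch = CnnArchitecture(input_height=26, n_classes=3)
        cfg = TrainConfig(epochs=5, seed=7)
        m1, c1, h1 = train_cnn(images, cfg, arch=arch)
        m2, c2, h2 = train_cnn(images, cfg, arch=arch)
        np.testing.assert_array_equal(c1.centers, c2.centers)
        assert [r.joint_loss for r in h1] == [r.joint_loss for r in h2]
        s1, s2 = m1.net.state_arrays(), m2.net.state_arrays()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_single_class_rejected(self):
        images = [img for img in small_dataset() if img.label == "C0"]
        with pytest.raises(ClassifierError, match="classes"):
            train_cnn(images, TrainConfig(epochs=1))

    def test_checkpoint_round_trip(self, trained, tmp_path):
        images, (model, centers, history) = trained
        path = tmp_path / "cnn.npz"
        model.save(path)
        back = CnnClassifier.load(path)
        f1 = model.extract_features(images[:3])
        f2 = back.extract_features(images[:3])
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.vector, b.vector)
        assert back.fingerprint() == model.fingerprint()
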