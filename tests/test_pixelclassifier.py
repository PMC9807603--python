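"""Pixel sampling contracts, classifier training behaviour (separable
benchmark, determinism, early stopping) and prediction invariants."""

import numpy as np
import pytest

from blastoseg.features import FeatureStack, N_FEATURES
from blastoseg.pixelclassifier import (ClassifierSpec, InitialSegmentation,
                                       PixelSampleSet, REGION_CODES,
                                       predict_pixels, sample_training_pixels,
                                       train_pixel_classifier)


def fake_stack(h, w, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureStack(values=rng.random((h, w, N_FEATURES)).astype(np.float32),
                        feature_names=tuple(f"f{i}" for i in range(N_FEATURES)),
                        bank_version="fb-test", kernel_version="ks-test")


class TestSampling:
    def test_50_per_region_when_all_present(self, expansion_phantom):
        _, labels = expansion_phantom
        stack = fake_stack(*labels.shape)
        s = sample_training_pixels(stack, labels, n_per_region=50, seed=0)
        assert len(s.labels) == 250
        counts = np.bincount(s.labels, minlength=5)
        assert (counts == 50).all()

    def test_absent_region_contributes_zero_rows(self, expansion_phantom):
        _, labels = expansion_phantom
        no_icm = np.where(labels == REGION_CODES["ICM"],
                          REGION_CODES["BC"], labels)
        stack = fake_stack(*labels.shape)
        s = sample_training_pixels(stack, no_icm, seed=0)
        counts = np.bincount(s.labels, minlength=5)
        assert counts[REGION_CODES["ICM"]] == 0
        assert len(s.labels) == 200

    def test_small_region_capped_at_its_size(self):
        labels = np.zeros((40, 40), dtype=np.uint8)
        labels[:4, :3] = REGION_CODES["ICM"]           # 12 pixels
        stack = fake_stack(40, 40)
        s = sample_training_pixels(stack, labels, n_per_region=50, seed=1)
        assert np.count_nonzero(s.labels == REGION_CODES["ICM"]) == 12

    def test_sampling_without_replacement(self):
        labels = np.zeros((20, 20), dtype=np.uint8)
        labels[:10] = REGION_CODES["TE"]
        stack = fake_stack(20, 20)
        s = sample_training_pixels(stack, labels, n_per_region=50, seed=2)
        coords = [(x, y) for _, x, y in s.provenance]
        assert len(coords) == len(set(coords))

    def test_deterministic_under_seed(self, expansion_phantom):
        _, labels = expansion_phantom
        stack = fake_stack(*labels.shape)
        a = sample_training_pixels(stack, labels, seed=7)
        b = sample_training_pixels(stack, labels, seed=7)
        assert np.array_equal(a.features, b.features)
        assert a.provenance == b.provenance

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            sample_training_pixels(fake_stack(10, 10), np.zeros((12, 12)))


def separable_samples(n_per_class=120, seed=0):
    """Five well-separated Gaussian blobs in the 861-dim feature space."""
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for c in range(5):
        center = np.zeros(N_FEATURES)
        center[c * 10:(c + 1) * 10] = 6.0
        feats.append(center + rng.normal(0, 0.5, (n_per_class, N_FEATURES)))
        labels.append(np.full(n_per_class, c))
    return PixelSampleSet(features=np.concatenate(feats).astype(np.float32),
                          labels=np.concatenate(labels))


class TestTraining:
    def test_separable_blobs_reach_high_accuracy(self):
        samples = separable_samples()
        spec = ClassifierSpec(epochs=30, units_per_layer=64, batch_size=64, seed=0)
        model = train_pixel_classifier(samples, spec)
        scores = model.predict_scores(samples.features)
        acc = (scores.argmax(1) == samples.labels).mean()
        assert acc > 0.95

    def test_agrees_with_independent_classifier(self):
        """Cross-check against scikit-learn's MLP on the same separable
        problem: both learners must solve it."""
        from sklearn.neural_network import MLPClassifier
        samples = separable_samples(seed=3)
        sk = MLPClassifier(hidden_layer_sizes=(64,), max_iter=300, random_state=0)
        sk.fit(samples.features, samples.labels)
        assert sk.score(samples.features, samples.labels) > 0.95
        spec = ClassifierSpec(epochs=30, units_per_layer=64, batch_size=64, seed=0)
        model = train_pixel_classifier(samples, spec)
        ours = model.predict_scores(samples.features).argmax(1)
        assert (ours == sk.predict(samples.features)).mean() > 0.95

    def test_identical_seed_identical_first_epoch_loss(self):
        samples = separable_samples(seed=1)
        spec = ClassifierSpec(epochs=2, units_per_layer=32, seed=5)
        h1 = train_pixel_classifier(samples, spec).history
        h2 = train_pixel_classifier(samples, spec).history
        assert h1["loss"][0] == h2["loss"][0]

    def test_early_stopping_halts_before_cap(self):
        """A constant-feature problem cannot improve validation loss, so the
        early-stopping callback (patience, min delta) must end training well
        before the epoch cap."""
        rng = np.random.default_rng(0)
        feats = np.zeros((400, N_FEATURES), dtype=np.float32)
        labels = rng.integers(0, 5, 400)
        samples = PixelSampleSet(features=feats, labels=labels)
        spec = ClassifierSpec(epochs=200, units_per_layer=16, batch_size=128,
                              early_stopping_patience=10, seed=0)
        model = train_pixel_classifier(samples, spec)
        assert len(model.history["loss"]) < 200

    def test_lr_reduction_on_plateau(self):
        rng = np.random.default_rng(0)
        samples = PixelSampleSet(
            features=np.zeros((300, N_FEATURES), dtype=np.float32),
            labels=rng.integers(0, 5, 300))
        spec = ClassifierSpec(epochs=40, units_per_layer=8,
                              lr_reduction_patience=5,
                              early_stopping_patience=60, seed=0)
        model = train_pixel_classifier(samples, spec)
        lrs = model.history["lr"]
        assert lrs[-1] < lrs[0]

    def test_single_class_rejected(self):
        samples = PixelSampleSet(
            features=np.zeros((50, N_FEATURES), dtype=np.float32),
            labels=np.zeros(50, dtype=np.int64))
        with pytest.raises(ValueError, match="two classes"):
            train_pixel_classifier(samples)


class TestPrediction:
    @pytest.fixture(scope="class")
    def trained(self):
        return train_pixel_classifier(
            separable_samples(),
            ClassifierSpec(epochs=20, units_per_layer=32, batch_size=64, seed=0))

    def test_scores_are_distributions_and_maps_partition(self, trained):
        stack = fake_stack(16, 16, seed=4)
        seg = predict_pixels(trained, stack)
        assert seg.score_maps.shape == (16, 16, 5)
        assert np.allclose(seg.score_maps.sum(-1), 1.0, atol=1e-5)
        assert seg.binary_maps.sum(-1).max() == 1       # exactly one label each

    def test_tie_break_uses_priority_order(self):
        scores = np.full((2, 2, 5), 0.2, dtype=np.float32)
        seg = InitialSegmentation(score_maps=scores)
        assert (seg.labels == REGION_CODES["BG"]).all()

    def test_depth_mismatch_rejected(self, trained):
        bad = FeatureStack(values=np.zeros((8, 8, 10), dtype=np.float32),
                           feature_names=tuple(str(i) for i in range(10)),
                           bank_version="x", kernel_version="y")
        with pytest.raises(ValueError, match="depth"):
            predict_pixels(trained, bad)
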