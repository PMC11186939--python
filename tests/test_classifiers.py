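"""Classifier construction, balanced training, persistence, prediction."""

import numpy as np
import pytest

from neoecho.classifiers import (
    TrainConfig,
    _argmax_high_severity,
    build_model,
    compute_sample_weights,
    load_classifier,
    predict,
    save_classifier,
    train_classifier,
)
from neoecho.types import ValidationError


def _toy_samples(n_per_class=6, k=4, size=16, seed=0):
    """Class-coded synthetic clips: intensity level identifies the class."""
    rng = np.random.default_rng(seed)
    samples = []
    for lab, level in enumerate((40, 130, 220)):
        for _ in range(n_per_class):
            clip = np.clip(
                rng.normal(level, 12, (k, size, size)), 0, 255
            ).astype(np.uint8)
            samples.append((clip, lab))
    return samples


class TestBuildModel:
    def test_variants_and_logit_shapes(self):
        x3 = [np.zeros((12, 32, 32), np.uint8)]
        for variant in ("tiny_3d", "spatiotemporal_3d"):
            clf = build_model(variant, num_classes=3, seed=0)
            assert clf.logits(x3).shape == (1, 3)
        clf2d = build_model("spatial_2d", num_classes=3, seed=0)
        assert clf2d.logits([np.zeros((32, 32), np.uint8)]).shape == (1, 3)

    def test_unknown_variant(self):
        with pytest.raises(ValidationError):
            build_model("lstm")

    def test_pretrained_true_raises(self):
        # no weights ship with the package
        with pytest.raises(ValidationError, match="no weights"):
            build_model("tiny_3d", pretrained=True)

    def test_input_shape_validation(self):
        clf = build_model("tiny_3d", seed=0)
        with pytest.raises(ValidationError):
            clf.prepare_batch([np.zeros((32, 32), np.uint8)])  # frame, not clip
        clf2d = build_model("spatial_2d", seed=0)
        with pytest.raises(ValidationError):
            clf2d.prepare_batch([np.zeros((4, 32, 32), np.uint8)])

    def test_normalization_contract(self):
        clf = build_model("tiny_3d", mean=0.5, std=0.25, seed=0)
        x = clf.prepare_batch([np.full((2, 16, 16), 255, np.uint8)])
        assert x.shape == (1, 1, 2, 16, 16)
        assert np.allclose(x, (1.0 - 0.5) / 0.25)


class TestSampleWeights:
    def test_inverse_counts(self):
        w = compute_sample_weights([0, 0, 1])
        assert np.allclose(w, [0.5, 0.5, 1.0])

    def test_balances_expected_draws(self):
        labels = [0] * 8 + [1] * 2
        w = compute_sample_weights(labels)
        p = w / w.sum()
        assert p[:8].sum() == pytest.approx(0.5)
        assert p[8:].sum() == pytest.approx(0.5)

    def test_sampler_class_balance_3sigma(self):
        labels = np.array([0] * 30 + [1] * 6 + [2] * 4)
        w = compute_sample_weights(labels)
        p = w / w.sum()
        rng = np.random.default_rng(0)
        n = 6000
        draws = labels[rng.choice(len(labels), size=n, replace=True, p=p)]
        for lab in (0, 1, 2):
            frac = (draws == lab).mean()
            assert abs(frac - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / n)

    def test_empty(self):
        with pytest.raises(ValidationError):
            compute_sample_weights([])


class TestTraining:
    def test_config_validation(self):
        with pytest.raises(ValidationError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValidationError):
            TrainConfig(epochs=0)
        with pytest.raises(ValidationError):
            TrainConfig(num_classes=5)

    def test_defaults_match_study_settings(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 0.001
        assert cfg.weight_decay == 0.001
        assert cfg.epochs == 150

    def test_memorizes_toy_problem(self):
        samples = _toy_samples()
        clf = build_model("tiny_3d", mean=0.5, std=0.3, seed=1)
        hist = train_classifier(
            clf, samples, TrainConfig(epochs=10, seed=1),
            rng=np.random.default_rng(1),
        )
        assert hist["loss"][-1] < hist["loss"][0]
        probs, labels = predict(clf, [s for s, _ in samples])
        truth = np.array([l for _, l in samples])
        assert (labels == truth).mean() == 1.0
        assert probs.shape == (len(samples), 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_training_deterministic(self):
        samples = _toy_samples(n_per_class=3)
        losses = []
        for _ in range(2):
            clf = build_model("tiny_3d", seed=5)
            h = train_classifier(clf, samples, TrainConfig(epochs=2, seed=5),
                                 rng=np.random.default_rng(5))
            losses.append(h["loss"])
        assert losses[0] == losses[1]

    def test_single_class_rejected(self):
        samples = [(np.zeros((4, 16, 16), np.uint8), 1)] * 4
        clf = build_model("tiny_3d", seed=0)
        with pytest.raises(ValidationError):
            train_classifier(clf, samples, TrainConfig(epochs=1))

    def test_label_outside_range_rejected(self):
        clf = build_model("tiny_3d", num_classes=2, seed=0)
        samples = [(np.zeros((4, 16, 16), np.uint8), 0),
                   (np.zeros((4, 16, 16), np.uint8), 2)]
        with pytest.raises(ValidationError):
            train_classifier(clf, samples, TrainConfig(epochs=1, num_classes=2))


class TestPrediction:
    def test_tie_breaks_toward_higher_severity(self):
        probs = np.array([
            [0.5, 0.5, 0.0],
            [0.2, 0.4, 0.4],
            [1 / 3, 1 / 3, 1 / 3],
            [0.9, 0.05, 0.05],
        ])
        assert _argmax_high_severity(probs).tolist() == [1, 2, 2, 0]


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        samples = _toy_samples(n_per_class=2)
        clf = build_model("tiny_3d", mean=0.4, std=0.3, seed=2)
        train_classifier(clf, samples, TrainConfig(epochs=1, seed=2),
                         rng=np.random.default_rng(2))
        p = tmp_path / "model.npz"
        save_classifier(clf, p)
        back = load_classifier(p)
        assert back.variant == "tiny_3d"
        assert back.mean == 0.4 and back.std == 0.3
        x = [s for s, _ in samples[:4]]
        assert np.allclose(back.predict_proba(x), clf.predict_proba(x), atol=1e-6)

    def test_load_into_build_model(self, tmp_path):
        clf = build_model("tiny_3d", seed=3)
        p = tmp_path / "m.npz"
        save_classifier(clf, p)
        again = build_model("tiny_3d", pretrained=str(p), seed=99)
        x = [np.full((4, 16, 16), 77, np.uint8)]
        assert np.allclose(again.predict_proba(x), clf.predict_proba(x), atol=1e-6)
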