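"""Backbone construction, freezing, training and score prediction."""

import numpy as np
import pytest

from hfus_iqa import (
    OK,
    NO_OK,
    TrainConfig,
    build_model,
    desk_scale_config,
    generate_frame,
    predict_scores,
    score_to_ok_probability,
    train,
)


def _tiny_cfg(**kw):
    return desk_scale_config(**kw)


def _separable_frames(n_per_class, seed):
    """Unambiguously good vs probe-in-air frames (constructed separable)."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for _ in range(n_per_class):
        X.append(generate_frame("correct", rng).pixels)
        y.append(OK)
        X.append(generate_frame("no_contact", rng).pixels)
        y.append(NO_OK)
    return np.stack(X), y


class TestBuildModel:
    @pytest.mark.parametrize(
        "backbone,n_convs,n_frozen", [("vgg16", 13, 10), ("densenet201", 200, 140), ("tiny_test", 2, 0)]
    )
    def test_conv_counts_and_freeze_mask(self, backbone, n_convs, n_frozen):
        model = build_model(TrainConfig(backbone=backbone, n_classes=2, seed=0))
        convs = model.conv_layers()
        assert len(convs) == n_convs
        assert [not c.W.trainable for c in convs] == [i < n_frozen for i in range(n_convs)]

    def test_unknown_backbone_and_bad_freeze(self):
        with pytest.raises(ValueError, match="backbone"):
            TrainConfig(backbone="resnet50")
        with pytest.raises(ValueError, match="freeze"):
            build_model(TrainConfig(backbone="tiny_test", frozen_conv_layers=99))

    def test_n_classes_validated(self):
        with pytest.raises(ValueError):
            TrainConfig(n_classes=3)


class TestTraining:
    def test_tiny_test_learns_separable_classes(self):
        """>0.9 held-out accuracy on unambiguous good vs no-contact frames."""
        X, y = _separable_frames(30, seed=0)
        cfg = _tiny_cfg(seed=0, epochs=5)
        model = build_model(cfg)
        train(model, (X[:40], y[:40]), None, cfg)
        scores = predict_scores(model, X[40:])
        preds = [model.class_order[i] for i in scores.argmax(axis=1)]
        acc = np.mean([p == t for p, t in zip(preds, y[40:])])
        assert acc > 0.9

    def test_zero_epochs_is_identity(self):
        X, y = _separable_frames(3, seed=1)
        cfg = _tiny_cfg(seed=0, epochs=0)
        model = build_model(cfg)
        digest = model.weights_digest()
        log = train(model, (X, y), None, cfg)
        assert log == []
        assert model.weights_digest() == digest

    def test_same_seed_same_weights(self):
        X, y = _separable_frames(5, seed=2)
        digests = []
        for _ in range(2):
            cfg = _tiny_cfg(seed=123, epochs=3)
            model = build_model(cfg)
            train(model, (X, y), None, cfg)
            digests.append(model.weights_digest())
        assert digests[0] == digests[1]

    def test_log_has_one_entry_per_epoch(self):
        X, y = _separable_frames(5, seed=3)
        cfg = _tiny_cfg(seed=0, epochs=4)
        model = build_model(cfg)
        log = train(model, (X[:8], y[:8]), (X[8:], y[8:]), cfg)
        assert len(log) == 4
        assert all({"loss", "acc", "val_loss", "val_acc"} <= set(e) for e in log)

    def test_empty_train_set_and_bad_labels(self):
        cfg = _tiny_cfg(seed=0, epochs=1)
        model = build_model(cfg)
        with pytest.raises(ValueError, match="empty"):
            train(model, (np.empty((0, 224, 224, 3)), []), None, cfg)
        X, _ = _separable_frames(2, seed=4)
        with pytest.raises(ValueError, match="class order"):
            train(model, (X, [1, 2, 3, 4]), None, cfg)

    @pytest.mark.parametrize("backbone", ["vgg16", "densenet201"])
    def test_frozen_layers_bit_identical_after_training(self, backbone):
        """A training step must not touch the frozen convolution weights."""
        cfg = TrainConfig(backbone=backbone, n_classes=2, epochs=1, batch_size=2, seed=0)
        model = build_model(cfg)
        convs = model.conv_layers()
        frozen_before = [c.W.value.copy() for c in convs[: cfg.frozen]]
        head_before = model.net.params()[-2].value.copy()
        rng = np.random.default_rng(0)
        X = rng.integers(0, 255, size=(4, 32, 32, 3)).astype(np.uint8)
        train(model, (X, [OK, NO_OK, OK, NO_OK]), None, cfg)
        for before, conv in zip(frozen_before, convs[: cfg.frozen]):
            assert (before == conv.W.value).all()
        assert (head_before != model.net.params()[-2].value).any()  # the head did train


@pytest.fixture(scope="module")
def trained():
    X, y = _separable_frames(10, seed=5)
    cfg = _tiny_cfg(seed=0, epochs=3)
    model = build_model(cfg)
    train(model, (X, y), None, cfg)
    return model, X


class TestPrediction:

    def test_scores_normalized_and_shaped(self, trained):
        model, X = trained
        scores = predict_scores(model, X[:7])
        assert scores.shape == (7, 2)
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-6)
        assert (scores >= 0).all()

    def test_duplicated_frame_identical_scores(self, trained):
        model, X = trained
        s = predict_scores(model, np.stack([X[0], X[0]]))
        assert (s[0] == s[1]).all()

    def test_ok_probability(self):
        assert score_to_ok_probability(np.array([0.2, 0.8])) == pytest.approx(0.8)
        assert score_to_ok_probability(np.array([1.0, 0.0])) == 0.0
        batch = np.array([[0.3, 0.7], [0.9, 0.1]])
        assert np.allclose(score_to_ok_probability(batch) + batch[:, 0], 1.0)
        with pytest.raises(ValueError):
            score_to_ok_probability(np.array([0.2, 0.3, 0.5]))

    def test_checkpoint_round_trip(self, trained, tmp_path):
        model, X = trained
        before = predict_scores(model, X[:3])
        model.save(tmp_path / "m.npz")
        fresh = build_model(_tiny_cfg(seed=99, epochs=3))
        fresh.load(tmp_path / "m.npz")
        assert np.allclose(predict_scores(fresh, X[:3]), before)
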