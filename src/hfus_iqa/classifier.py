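"""Backbone-agnostic CNN classification of HFUS frames.

Three backbones are expressed:

* ``vgg16`` — the 13-convolution VGG-16 topology with the transfer-learning
  configuration used for this task (first 10 convolution layers frozen, new
  classification head);
* ``densenet201`` — the 200-convolution DenseNet-201 topology (first 140
  convolution layers frozen);
* ``tiny_test`` — a small fully trainable network (block-mean stem + two
  convolution blocks) for desk-scale experiments on synthetic data.

All backbones run on the package's own NumPy layer engine, so no deep
learning framework is required; ImageNet-pretrained weights are not bundled
(a checkpoint produced elsewhere can be loaded with
:meth:`HfusClassifier.load`), which means the large backbones start from
random initialisation.  Training uses the regime shared by the binary and
multi-class experiments: SGD with momentum 0.9, categorical cross-entropy,
batch size 64, learning rate 1e-4, 50 epochs.

Class-score vectors are softmax outputs; for binary models the class order
is fixed as (no_ok, ok), so ``scores[1]`` is the probability of 'ok' fed to
the fuzzy voting step.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _net
from .label_fusion import OK, NO_OK, BinaryLabel

__all__ = [
    "TrainConfig",
    "HfusClassifier",
    "build_model",
    "train",
    "predict_scores",
    "score_to_ok_probability",
    "desk_scale_config",
    "BINARY_CLASS_ORDER",
    "GROUP_CLASS_ORDER",
]

#: Class order of binary score vectors: index 0 = no_ok, index 1 = ok.
BINARY_CLASS_ORDER: tuple[BinaryLabel, BinaryLabel] = (NO_OK, OK)

#: Class order of 4-group score vectors.
GROUP_CLASS_ORDER: tuple[int, int, int, int] = (1, 2, 3, 4)

#: Default number of frozen convolution layers per backbone (convolutions
#: counted in definition order).
DEFAULT_FROZEN = {"vgg16": 10, "densenet201": 140, "tiny_test": 0}

#: ImageNet channel statistics used to standardise inputs of the
#: transfer-learning backbones.
_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration; defaults are the shared transfer-learning regime."""

    backbone: str = "vgg16"
    n_classes: int = 2
    frozen_conv_layers: int | None = None  # None -> backbone default
    learning_rate: float = 1e-4  # initial; decayed stepwise, see lr_decay
    lr_decay: float = 0.3  # multiplier applied at 1/3 and 2/3 of the epochs
    momentum: float = 0.9
    batch_size: int = 64
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in DEFAULT_FROZEN:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; choose from {sorted(DEFAULT_FROZEN)}"
            )
        if self.n_classes not in (2, 4):
            raise ValueError(f"n_classes must be 2 or 4, got {self.n_classes}")
        if self.frozen_conv_layers is not None and self.frozen_conv_layers < 0:
            raise ValueError("frozen_conv_layers must be >= 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")

    @property
    def frozen(self) -> int:
        return (
            self.frozen_conv_layers
            if self.frozen_conv_layers is not None
            else DEFAULT_FROZEN[self.backbone]
        )


def desk_scale_config(n_classes: int = 2, seed: int = 0, epochs: int = 15) -> TrainConfig:
    """tiny_test configuration for CPU-scale runs on synthetic data.

    The from-scratch tiny network needs a larger step size than the
    fine-tuning regime of the pretrained backbones; 0.05 with momentum 0.9
    trains it to convergence in ~15 epochs on the synthetic classes.
    """
    return TrainConfig(
        backbone="tiny_test",
        n_classes=n_classes,
        learning_rate=0.05,
        epochs=epochs,
        seed=seed,
    )


# -- backbone builders ----------------------------------------------------

_VGG16_PLAN = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, "M", 512, 512, 512, "M"]


def _build_vgg16(n_classes: int, rng: np.random.Generator) -> _net.Sequential:
    layers: list[_net.Layer] = []
    in_ch, i = 3, 0
    for item in _VGG16_PLAN:
        if item == "M":
            layers.append(_net.MaxPool2D(2))
        else:
            layers.append(_net.Conv2D(in_ch, item, 3, pad=1, rng=rng, name=f"conv{i}"))
            layers.append(_net.ReLU())
            in_ch, i = item, i + 1
    layers += [_net.GlobalAvgPool(), _net.Dense(512, n_classes, rng=rng, name="head")]
    return _net.Sequential(layers)


def _build_densenet201(n_classes: int, rng: np.random.Generator) -> _net.Sequential:
    growth, bn_size = 32, 4
    block_sizes = (6, 12, 48, 32)

    def unit(in_ch: int, idx: str) -> _net.Sequential:
        return _net.Sequential([
            _net.BatchNorm(in_ch, name=f"{idx}.bn1"),
            _net.ReLU(),
            _net.Conv2D(in_ch, bn_size * growth, 1, rng=rng, name=f"{idx}.conv1"),
            _net.BatchNorm(bn_size * growth, name=f"{idx}.bn2"),
            _net.ReLU(),
            _net.Conv2D(bn_size * growth, growth, 3, pad=1, rng=rng, name=f"{idx}.conv2"),
        ])

    layers: list[_net.Layer] = [
        _net.Conv2D(3, 64, 7, stride=2, pad=3, rng=rng, name="stem.conv"),
        _net.BatchNorm(64, name="stem.bn"),
        _net.ReLU(),
        _net.MaxPool2D(3, stride=2, pad=1),
    ]
    ch = 64
    for b, n_units in enumerate(block_sizes):
        units = []
        for u in range(n_units):
            units.append(unit(ch + u * growth, f"block{b}.unit{u}"))
        layers.append(_net.DenseBlock(units))
        ch += n_units * growth
        if b < len(block_sizes) - 1:
            layers.append(_net.Sequential([
                _net.BatchNorm(ch, name=f"trans{b}.bn"),
                _net.ReLU(),
                _net.Conv2D(ch, ch // 2, 1, rng=rng, name=f"trans{b}.conv"),
                _net.AvgPool2D(2),
            ]))
            ch //= 2
    layers += [
        _net.BatchNorm(ch, name="final.bn"),
        _net.ReLU(),
        _net.GlobalAvgPool(),
        _net.Dense(ch, n_classes, rng=rng, name="head"),
    ]
    return _net.Sequential(layers)


def _build_tiny(n_classes: int, rng: np.random.Generator) -> _net.Sequential:
    # Two small conv blocks on the 16 x 16 block-mean reduction computed in
    # preprocess().  The reduction keeps the entry-echo band, tilt, shadow
    # wedges and contrast statistics visible while making CPU training
    # near-instant.
    return _net.Sequential([
        _net.Conv2D(3, 8, 3, pad=1, rng=rng, name="conv0"),
        _net.ReLU(),
        _net.MaxPool2D(2),
        _net.Conv2D(8, 16, 3, pad=1, rng=rng, name="conv1"),
        _net.ReLU(),
        _net.MaxPool2D(2),
        _net.Flatten(),
        _net.Dense(4 * 4 * 16, 32, rng=rng, name="fc0"),
        _net.ReLU(),
        _net.Dense(32, n_classes, rng=rng, name="head"),
    ])


_BUILDERS = {"vgg16": _build_vgg16, "densenet201": _build_densenet201, "tiny_test": _build_tiny}


@dataclass
class HfusClassifier:
    """A built (possibly trained) backbone plus its configuration."""

    cfg: TrainConfig
    net: _net.Sequential

    def preprocess(self, frames: np.ndarray) -> np.ndarray:
        x = np.asarray(frames, dtype=np.float32) / 255.0
        if self.cfg.backbone in ("vgg16", "densenet201"):
            return (x - _IMAGENET_MEAN) / _IMAGENET_STD
        # tiny_test: fixed 16 x 16 block-mean reduction (needs divisible dims).
        n, h, w, c = x.shape
        if h % 16 or w % 16:
            raise ValueError(f"tiny_test needs spatial dims divisible by 16, got {h}x{w}")
        return x.reshape(n, 16, h // 16, 16, w // 16, c).mean(axis=(2, 4))

    @property
    def class_order(self) -> tuple:
        return BINARY_CLASS_ORDER if self.cfg.n_classes == 2 else GROUP_CLASS_ORDER

    def conv_layers(self) -> list[_net.Conv2D]:
        return self.net.conv_layers()

    def weights_digest(self) -> str:
        """SHA-256 over all parameter values (a compact identity for tests)."""
        h = hashlib.sha256()
        for p in self.net.params():
            h.update(np.ascontiguousarray(p.value).tobytes())
        return h.hexdigest()

    def save(self, path: str | Path) -> None:
        _net.save_params(self.net, path, meta={
            "backbone": self.cfg.backbone,
            "n_classes": self.cfg.n_classes,
            "frozen_conv_layers": self.cfg.frozen,
        })

    def load(self, path: str | Path) -> None:
        meta = _net.load_params(self.net, path)
        if meta and meta.get("backbone") != self.cfg.backbone:
            raise ValueError(
                f"checkpoint backbone {meta.get('backbone')!r} does not match {self.cfg.backbone!r}"
            )


def build_model(cfg: TrainConfig) -> HfusClassifier:
    """Construct the backbone with a fresh head and apply the freeze mask."""
    rng = np.random.default_rng(cfg.seed)
    net = _BUILDERS[cfg.backbone](cfg.n_classes, rng)
    convs = net.conv_layers()
    if cfg.frozen > len(convs):
        raise ValueError(
            f"cannot freeze {cfg.frozen} convolution layers: {cfg.backbone} has {len(convs)}"
        )
    for conv in convs[: cfg.frozen]:
        conv.W.trainable = False
        conv.b.trainable = False
    return HfusClassifier(cfg=cfg, net=net)


def _as_class_indices(labels: Sequence, class_order: Sequence) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_order)}
    try:
        return np.array([index[l] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in class order {tuple(class_order)}") from None


def train(
    model: HfusClassifier,
    train_set: tuple[np.ndarray, Sequence],
    val_set: tuple[np.ndarray, Sequence] | None,
    cfg: TrainConfig | None = None,
) -> list[dict]:
    """Train in place; returns a per-epoch log (one entry per epoch).

    ``train_set``/``val_set`` are ``(frames, labels)`` with labels drawn from
    the model's class order.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or model.cfg
    X, y = train_set
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(X) != len(y):
        raise ValueError(f"frames/labels mismatch: {len(X)} vs {len(y)}")
    yi = _as_class_indices(y, model.class_order)
    Xp = model.preprocess(X)
    onehot = np.eye(cfg.n_classes, dtype=np.float32)[yi]

    val = None
    if val_set is not None and len(val_set[0]) > 0:
        val = (model.preprocess(val_set[0]), _as_class_indices(val_set[1], model.class_order))

    opt = _net.SGDMomentum(model.net.params(), lr=cfg.learning_rate, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed)
    log: list[dict] = []
    n = len(Xp)
    # step-decay schedule: the configured rate is the *initial* one
    decay_at = {cfg.epochs // 3, 2 * cfg.epochs // 3} if cfg.epochs >= 3 else set()
    for epoch in range(cfg.epochs):
        if epoch in decay_at and epoch > 0:
            opt.lr *= cfg.lr_decay
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad(model.net.params())
            logits = model.net.forward(Xp[idx], train=True)
            loss, dlogits = _net.softmax_cross_entropy(logits, onehot[idx])
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yi[idx]).sum())
        entry = {"epoch": epoch, "loss": sum(losses) / n, "acc": correct / n}
        if val is not None:
            vlogits = model.net.forward(val[0], train=False)
            vloss, _ = _net.softmax_cross_entropy(
                vlogits, np.eye(cfg.n_classes, dtype=np.float32)[val[1]]
            )
            entry["val_loss"] = vloss
            entry["val_acc"] = float((vlogits.argmax(axis=1) == val[1]).mean())
        log.append(entry)
    return log


def predict_scores(model: HfusClassifier, frames: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Softmax class-score vectors, one row per frame (rows sum to 1)."""
    frames = np.asarray(frames)
    if frames.ndim == 3:
        frames = frames[None]
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError(f"expected (n, h, w, 3) frames, got shape {frames.shape}")
    Xp = model.preprocess(frames)
    chunks = []
    for start in range(0, len(Xp), batch_size):
        logits = model.net.forward(Xp[start : start + batch_size], train=False)
        chunks.append(_net.softmax(logits))
    return np.concatenate(chunks, axis=0)


def score_to_ok_probability(scores: np.ndarray) -> np.ndarray | float:
    """The 'ok'-class entry of binary score vectors (class order no_ok, ok)."""
    arr = np.asarray(scores, dtype=float)
    if arr.shape[-1] != 2:
        raise ValueError(f"'ok' probability is defined for binary scores, got {arr.shape[-1]} classes")
    out = arr[..., 1]
    return float(out) if out.ndim == 0 else out
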