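"""The eight HFUS quality-classification processing paths.

Binary paths (1–4) decide ok / no_ok; multi-class paths (5–8) assign the
4-level fused group label.  They differ in what the CNN models are trained
on and how multiple model outputs are combined:

====  =======================  ==========================================
path  training labels          output combination
====  =======================  ==========================================
1     unanimous frames only    single binary model, direct decision
2     majority-vote labels     single binary model, direct decision
3     one model per expert     crisp majority vote of the 3 predictions
4     one model per expert     Mamdani FIS over the 3 'ok' scores
5     fused group labels       single 4-class model, direct decision
6     unanimous frames only    'ok' score thresholded into the 4 bins
7     one model per expert     group label of the 3 predicted votes
8     one model per expert     FIS output thresholded into the 4 bins
====  =======================  ==========================================

Each ``run_path*`` function trains on ``train_idx`` (with ``val_idx`` for
monitoring) and classifies ``predict_idx``; by default it trains on, and
classifies, every frame.  The per-expert models of paths 3/4/7/8 share the
same split and get seeds ``base_seed + expert_index``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .classifier import (
    HfusClassifier,
    TrainConfig,
    build_model,
    predict_scores,
    score_to_ok_probability,
    train,
)
from .fuzzy_vote import FisSpec, default_binary_spec, default_four_class_spec, fis_output, map_output_to_group, threshold_binary
from .label_fusion import OK, NO_OK, AnnotationTriple, BinaryLabel, assign_group, group_to_binary, majority_vote

__all__ = ["PathResult", "run_path", "PATH_RUNNERS"] + [f"run_path{i}" for i in range(1, 9)]


@dataclass
class PathResult:
    """Per-frame outcome of one processing path."""

    path_id: int
    predictions: list  # BinaryLabel for paths 1-4, int group for 5-8
    raw_outputs: np.ndarray  # 'ok' score / FIS output per classified frame
    models: list[HfusClassifier]
    predict_idx: np.ndarray  # indices of the classified frames
    logs: list[list[dict]]

    @property
    def is_binary(self) -> bool:
        return self.path_id <= 4


def _as_pixel_array(frames: Sequence) -> np.ndarray:
    """Accept FrameRecord/SyntheticFrame lists or a raw (n,224,224,3) array."""
    if isinstance(frames, np.ndarray):
        return frames
    pixels = []
    for f in frames:
        pixels.append(f.pixels if hasattr(f, "pixels") and f.pixels is not None else f.record.pixels)
    return np.stack(pixels)


def _resolve_idx(idx, n: int) -> np.ndarray:
    return np.arange(n) if idx is None else np.asarray(idx, dtype=np.int64)


def _split_val(train_idx: np.ndarray, val_idx, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Default 4:1 train/validation split when no validation indices are given."""
    if val_idx is not None:
        return train_idx, np.asarray(val_idx, dtype=np.int64)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(train_idx)
    n_val = len(perm) // 5
    return perm[n_val:], perm[:n_val]


def _fit(X: np.ndarray, labels: Sequence, cfg: TrainConfig,
         train_idx: np.ndarray, val_idx: np.ndarray) -> tuple[HfusClassifier, list[dict]]:
    labels = np.asarray(labels, dtype=object)
    model = build_model(cfg)
    log = train(
        model,
        (X[train_idx], labels[train_idx]),
        (X[val_idx], labels[val_idx]) if len(val_idx) else None,
        cfg,
    )
    return model, log


def _reliable_subset(triples: Sequence[AnnotationTriple], idx: np.ndarray) -> np.ndarray:
    groups = np.array([assign_group(triples[i]) for i in idx])
    keep = idx[np.isin(groups, (1, 4))]
    if len(keep) == 0:
        raise ValueError("no reliable (unanimously annotated) frames in the training set")
    return keep


def _check_aligned(X: np.ndarray, triples: Sequence[AnnotationTriple]) -> None:
    if len(X) != len(triples):
        raise ValueError(f"frames and annotation triples misaligned: {len(X)} vs {len(triples)}")


# -- binary paths ---------------------------------------------------------

def run_path1(frames, triples, cfg: TrainConfig, *, train_idx=None, val_idx=None, predict_idx=None) -> PathResult:
    """Train on unanimous frames only; classify everything."""
    X = _as_pixel_array(frames)
    _check_aligned(X, triples)
    tr = _resolve_idx(train_idx, len(X))
    pr = _resolve_idx(predict_idx, len(X))
    tr, va = _split_val(_reliable_subset(triples, tr), val_idx, cfg.seed)
    labels = [group_to_binary(assign_group(t)) for t in triples]
    model, log = _fit(X, labels, replace(cfg, n_classes=2), tr, va)
    scores = predict_scores(model, X[pr])
    ok_p = score_to_ok_probability(scores)
    preds = [OK if p >= 0.5 else NO_OK for p in ok_p]
    return PathResult(1, preds, np.asarray(ok_p), [model], pr, [log])


def run_path2(frames, triples, cfg: TrainConfig, *, train_idx=None, val_idx=None, predict_idx=None) -> PathResult:
    """Train on all frames with majority-vote labels."""
    X = _as_pixel_array(frames)
    _check_aligned(X, triples)
    tr = _resolve_idx(train_idx, len(X))
    pr = _resolve_idx(predict_idx, len(X))
    tr, va = _split_val(tr, val_idx, cfg.seed)
    labels = [majority_vote(t.labels) for t in triples]
    model, log = _fit(X, labels, replace(cfg, n_classes=2), tr, va)
    ok_p = score_to_ok_probability(predict_scores(model, X[pr]))
    preds = [OK if p >= 0.5 else NO_OK for p in ok_p]
    return PathResult(2, preds, np.asarray(ok_p), [model], pr, [log])


def _per_expert_models(X, triples, cfg: TrainConfig, train_idx, val_idx):
    """Three binary models, one per expert column, sharing the fold split."""
    tr0 = _resolve_idx(train_idx, len(X))
    models, logs, scores = [], [], []
    for expert in range(3):
        tr, va = _split_val(tr0, val_idx, cfg.seed)
        labels = [t.labels[expert] for t in triples]
        ecfg = replace(cfg, n_classes=2, seed=cfg.seed + expert)
        model, log = _fit(X, labels, ecfg, tr, va)
        models.append(model)
        logs.append(log)
    return models, logs


def _expert_ok_probs(models, X, predict_idx) -> np.ndarray:
    return np.column_stack(
        [score_to_ok_probability(predict_scores(m, X[predict_idx])) for m in models]
    )


def run_path3(frames, triples, cfg: TrainConfig, *, train_idx=None, val_idx=None, predict_idx=None) -> PathResult:
    """Per-expert models combined by crisp majority vote of their decisions."""
    X = _as_pixel_array(frames)
    _check_aligned(X, triples)
    pr = _resolve_idx(predict_idx, len(X))
    models, logs = _per_expert_models(X, triples, cfg, train_idx, val_idx)
    ok_p = _expert_ok_probs(models, X, pr)
    votes = np.where(ok_p >= 0.5, 1, 0)
    preds = [majority_vote([OK if v else NO_OK for v in row]) for row in votes]
    return PathResult(3, preds, ok_p, models, pr, logs)


def run_path4(frames, triples, cfg: TrainConfig, *, fis: FisSpec | None = None,
              train_idx=None, val_idx=None, predict_idx=None) -> PathResult:
    """Per-expert models combined by the Mamdani FIS, thresholded at 0.5."""
    fis = fis or default_binary_spec()
    X = _as_pixel_array(frames)
    _check_aligned(X, triples)
    pr = _resolve_idx(predict_idx, len(X))
    models, logs = _per_expert_models(X, triples, cfg, train_idx, val_idx)
    ok_p = _expert_ok_probs(models, X, pr)
    outputs = np.array([fis_output(row, fis) for row in ok_p])
    preds = [threshold_binary(y) for y in outputs]
    return PathResult(4, preds, outputs, models, pr, logs)


# -- multi-class paths ----------------------------------------------------

def run_path5(frames, triples, cfg: TrainConfig, *, train_idx=None, val_idx=None, predict_idx=None) -> PathResult:
    """Direct 4-class model on the fused group labels."""
    X = _as_pixel_array(frames)
    _check_aligned(X, triples)
    tr = _resolve_idx(train_idx, len(X))
    pr = _resolve_idx(predict_idx, len(X))
    tr, va = _split_val(tr, val_idx, cfg.seed)
    labels = [assign_group(t) for t in triples]
    present = set(np.asarray(labels, dtype=object)[tr].tolist())
    if present != {1, 2, 3, 4}:
        warnings.warn(
            f"groups {sorted({1, 2, 3, 4} - present)} absent from the training fold; "
            "training proceeds on the remaining classes",
            stacklevel=2,
        )
    model, log = _fit(X, labels, replace(cfg, n_classes=4), tr, va)
    scores = predict_scores(model, X[pr])
    preds = [int(scores[i].argmax()) + 1 for i in range(len(pr))]
    return PathResult(5, preds, scores.max(axis=1), [model], pr, [log])


def run_path6(frames, triples, cfg: TrainConfig, *, train_idx=None, val_idx=None, predict_idx=None) -> PathResult:
    """Binary model trained on unanimous frames; 'ok' score mapped to the 4 bins."""
    X = _as_pixel_array(frames)
    _check_aligned(X, triples)
    tr = _resolve_idx(train_idx, len(X))
    pr = _resolve_idx(predict_idx, len(X))
    tr, va = _split_val(_reliable_subset(triples, tr), val_idx, cfg.seed)
    labels = [group_to_binary(assign_group(t)) for t in triples]
    model, log = _fit(X, labels, replace(cfg, n_classes=2), tr, va)
    ok_p = np.asarray(score_to_ok_probability(predict_scores(model, X[pr])))
    preds = [map_output_to_group(p) for p in ok_p]
    return PathResult(6, preds, ok_p, [model], pr, [log])


def run_path7(frames, triples, cfg: TrainConfig, *, train_idx=None, val_idx=None, predict_idx=None) -> PathResult:
    """Per-expert models; the 3 predicted votes are fused like expert votes."""
    X = _as_pixel_array(frames)
    _check_aligned(X, triples)
    pr = _resolve_idx(predict_idx, len(X))
    models, logs = _per_expert_models(X, triples, cfg, train_idx, val_idx)
    ok_p = _expert_ok_probs(models, X, pr)
    preds = [
        assign_group([OK if p >= 0.5 else NO_OK for p in row]) for row in ok_p
    ]
    return PathResult(7, preds, ok_p, models, pr, logs)


def run_path8(frames, triples, cfg: TrainConfig, *, fis: FisSpec | None = None,
              train_idx=None, val_idx=None, predict_idx=None) -> PathResult:
    """Per-expert models; the FIS output is thresholded into the 4 bins."""
    fis = fis or default_four_class_spec()
    X = _as_pixel_array(frames)
    _check_aligned(X, triples)
    pr = _resolve_idx(predict_idx, len(X))
    models, logs = _per_expert_models(X, triples, cfg, train_idx, val_idx)
    ok_p = _expert_ok_probs(models, X, pr)
    outputs = np.array([fis_output(row, fis) for row in ok_p])
    preds = [map_output_to_group(y) for y in outputs]
    return PathResult(8, preds, outputs, models, pr, logs)


PATH_RUNNERS = {
    1: run_path1, 2: run_path2, 3: run_path3, 4: run_path4,
    5: run_path5, 6: run_path6, 7: run_path7, 8: run_path8,
}


def run_path(path_id: int, frames, triples, cfg: TrainConfig, **kwargs) -> PathResult:
    """Dispatch to one of the eight processing paths."""
    if path_id not in PATH_RUNNERS:
        raise ValueError(f"path id must be in 1..8, got {path_id}")
    return PATH_RUNNERS[path_id](frames, triples, cfg, **kwargs)
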