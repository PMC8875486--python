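"""Cross-validated evaluation of the classification paths.

External k-fold (default 5) cross-validation: each fold's frames are
classified by models trained on the remaining frames, which are themselves
split 4:1 into training and validation.  Metrics are accuracy, precision,
recall and f1 (positive class 'ok' for binary, macro-averaged for
multi-class), the confusion matrix, and the unweighted Cohen's kappa between
algorithm and expert reference with its Landis–Koch category.

The named evaluations pair a path with a reference rule: #1 scores the
unanimous-frames model on the unanimous frames only; #2/#3/#5/#6 score paths
1–4 against the majority-vote labels; #7–#10 score paths 5–8 against the
fused group labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .classifier import TrainConfig
from .fuzzy_vote import FisSpec
from .label_fusion import (
    OK,
    NO_OK,
    AnnotationTriple,
    BinaryLabel,
    assign_group,
    cohen_kappa,
    group_to_binary,
    interpret_kappa,
    majority_vote,
)
from .paths import PathResult, run_path

__all__ = [
    "FoldSplit",
    "EvalReport",
    "make_cv_folds",
    "compute_metrics",
    "evaluate_path",
    "reference_labels_for_evaluation",
    "cross_validate_path",
    "EVALUATIONS",
]

#: Evaluation id -> (path id, reference rule).  #1 is the reliable-subset
#: check of the unanimous-frames model; #4 (the per-expert backbone
#: comparison) is not an aggregate evaluation and is exposed separately.
EVALUATIONS = {
    1: (1, "reliable"),
    2: (1, "binary"),
    3: (2, "binary"),
    5: (3, "binary"),
    6: (4, "binary"),
    7: (5, "group"),
    8: (6, "group"),
    9: (7, "group"),
    10: (8, "group"),
}


@dataclass(frozen=True)
class FoldSplit:
    """External k-fold assignment with nested 4:1 train/validation splits."""

    k: int
    test: tuple[np.ndarray, ...]
    train: tuple[np.ndarray, ...]
    val: tuple[np.ndarray, ...]

    @property
    def n(self) -> int:
        return sum(len(t) for t in self.test)


@dataclass(frozen=True)
class EvalReport:
    """Metrics of one evaluation."""

    confusion: np.ndarray
    labels: tuple
    acc: float
    precision: float
    recall: float
    f1: float
    kappa: float
    agreement: str
    n: int


def make_cv_folds(n: int, k: int = 5, seed: int = 0) -> FoldSplit:
    """Shuffled k-fold partition of ``n`` frames with nested 4:1 splits.

    Test folds partition the frames with sizes differing by at most one;
    within each fold's non-test frames, one fifth (rounded) is held out for
    validation.
    """
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} frames")
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = tuple(np.sort(f) for f in np.array_split(perm, k))
    train, val = [], []
    for fold in test:
        rest = rng.permutation(np.setdiff1d(perm, fold))
        n_val = round(len(rest) / 5)
        val.append(np.sort(rest[:n_val]))
        train.append(np.sort(rest[n_val:]))
    return FoldSplit(k=k, test=test, train=tuple(train), val=tuple(val))


def compute_metrics(y_true: Sequence, y_pred: Sequence, labels: Sequence,
                    positive=OK) -> EvalReport:
    """Confusion matrix, ACC/precision/recall/f1 and kappa for one labeling.

    Binary problems report precision/recall/f1 of the positive ('ok') class;
    multi-class problems report macro averages.
    """
    if len(y_true) == 0:
        raise ValueError("cannot evaluate an empty label sequence")
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    labels = list(labels)
    m = _sk_confusion(list(y_true), list(y_pred), labels=labels)
    acc = float(np.trace(m)) / len(y_true)
    if len(labels) == 2:
        p, r, f1, _ = precision_recall_fscore_support(
            list(y_true), list(y_pred), labels=labels, pos_label=positive,
            average="binary", zero_division=0,
        )
    else:
        p, r, f1, _ = precision_recall_fscore_support(
            list(y_true), list(y_pred), labels=labels, average="macro", zero_division=0,
        )
    kappa = cohen_kappa(m)
    return EvalReport(
        confusion=m, labels=tuple(labels), acc=acc, precision=float(p), recall=float(r),
        f1=float(f1), kappa=kappa, agreement=interpret_kappa(kappa), n=len(y_true),
    )


def evaluate_path(result: PathResult, reference: Sequence) -> EvalReport:
    """Score a path's predictions against aligned reference labels."""
    if len(result.predictions) != len(reference):
        raise ValueError(
            f"predictions and references misaligned: {len(result.predictions)} vs {len(reference)}"
        )
    ref = list(reference)
    binary_ref = all(isinstance(x, BinaryLabel) for x in ref)
    if result.is_binary != binary_ref:
        raise ValueError(
            "arity mismatch: binary paths need binary references, group paths need group references"
        )
    labels = [NO_OK, OK] if result.is_binary else [1, 2, 3, 4]
    return compute_metrics(ref, result.predictions, labels)


def reference_labels_for_evaluation(
    eval_id: int, triples: Sequence[AnnotationTriple]
) -> tuple[np.ndarray, list]:
    """Frame indices and reference labels used by a named evaluation.

    #1 keeps only unanimously annotated frames (their shared label); binary
    evaluations use the majority vote; multi-class evaluations use the fused
    group label.
    """
    if eval_id not in EVALUATIONS:
        raise ValueError(f"unknown evaluation id {eval_id}; known: {sorted(EVALUATIONS)}")
    _, rule = EVALUATIONS[eval_id]
    groups = [assign_group(t) for t in triples]
    if rule == "reliable":
        idx = np.array([i for i, g in enumerate(groups) if g in (1, 4)], dtype=np.int64)
        return idx, [group_to_binary(groups[i]) for i in idx]
    idx = np.arange(len(triples), dtype=np.int64)
    if rule == "binary":
        return idx, [majority_vote(t.labels) for t in triples]
    return idx, groups


def cross_validate_path(
    path_id: int,
    frames,
    triples: Sequence[AnnotationTriple],
    cfg: TrainConfig,
    k: int = 5,
    seed: int = 0,
    fis: FisSpec | None = None,
) -> PathResult:
    """Run a path under external k-fold CV; stitch the held-out predictions.

    Every frame is classified exactly once, by the fold in which it is a
    test frame.  The per-fold models are discarded from the stitched result
    (the last fold's are kept for inspection).
    """
    n = len(triples)
    split = make_cv_folds(n, k=k, seed=seed)
    predictions: list = [None] * n
    raw = np.zeros(n, dtype=float)
    last = None
    for f in range(split.k):
        kwargs = dict(train_idx=split.train[f], val_idx=split.val[f], predict_idx=split.test[f])
        if fis is not None:
            kwargs["fis"] = fis
        last = run_path(path_id, frames, triples, cfg, **kwargs)
        for j, frame_idx in enumerate(split.test[f]):
            predictions[frame_idx] = last.predictions[j]
            raw[frame_idx] = (
                last.raw_outputs[j] if last.raw_outputs.ndim == 1 else last.raw_outputs[j].mean()
            )
    return PathResult(
        path_id=path_id,
        predictions=predictions,
        raw_outputs=raw,
        models=last.models if last else [],
        predict_idx=np.arange(n),
        logs=last.logs if last else [],
    )
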