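"""Fusion of multi-expert frame annotations and inter-observer agreement.

Each high-frequency ultrasound (HFUS) frame carries three binary expert
annotations ('ok' = suitable for further analysis, 'no ok' = not).  The three
votes are fused two ways:

* a four-level *group label* counting the 'no ok' votes
  (1 = unanimous 'no ok', 2 = one dissenting 'no ok',
  3 = two 'no ok', 4 = unanimous 'ok'), and
* a binary *majority vote* (groups 2 and 4 are 'ok', 1 and 3 are 'no ok').

Agreement between annotators (or between an algorithm and the fused
reference) is quantified with unweighted Cohen's kappa and reported with the
Landis–Koch verbal bands.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BinaryLabel",
    "AnnotationTriple",
    "AgreementReport",
    "OK",
    "NO_OK",
    "assign_group",
    "group_to_binary",
    "majority_vote",
    "confusion_matrix",
    "cohen_kappa",
    "interpret_kappa",
    "group_size_summary",
    "agreement_report",
]


class BinaryLabel(str, enum.Enum):
    """The two admissible frame annotations."""

    OK = "ok"
    NO_OK = "no_ok"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


OK = BinaryLabel.OK
NO_OK = BinaryLabel.NO_OK


@dataclass(frozen=True)
class AnnotationTriple:
    """Ordered labels of Expert 1, Expert 2 and Expert 3 for one frame.

    Expert 1 and Expert 2 are the same person annotating twice (a week
    apart); Expert 3 is a second person.  The order is kept because the
    per-expert classification paths train one model per column.
    """

    labels: tuple[BinaryLabel, BinaryLabel, BinaryLabel]

    def __post_init__(self) -> None:
        if len(self.labels) != 3:
            raise ValueError(f"an annotation triple needs exactly 3 labels, got {len(self.labels)}")
        if not all(isinstance(l, BinaryLabel) for l in self.labels):
            raise TypeError("labels must be BinaryLabel values")

    def __iter__(self):
        return iter(self.labels)

    @property
    def n_no_ok(self) -> int:
        return sum(1 for l in self.labels if l is NO_OK)


@dataclass(frozen=True)
class AgreementReport:
    """2x2 agreement between two binary labelings."""

    confusion: np.ndarray
    kappa: float
    category: str


def assign_group(triple: AnnotationTriple | Sequence[BinaryLabel]) -> int:
    """Fuse three expert votes into the 4-level group label.

    The group is a function of the number of 'no ok' votes:
    3 -> 1, 1 -> 2, 2 -> 3, 0 -> 4.  Total on all 8 vote combinations.
    """
    labels = list(triple)
    if len(labels) != 3:
        raise ValueError("group labels are defined for exactly three annotations")
    n_no = sum(1 for l in labels if BinaryLabel(l) is NO_OK)
    return {3: 1, 1: 2, 2: 3, 0: 4}[n_no]


def group_to_binary(group: int) -> BinaryLabel:
    """Majority-decision binary label of a group: {2, 4} -> ok, {1, 3} -> no_ok."""
    if group in (2, 4):
        return OK
    if group in (1, 3):
        return NO_OK
    raise ValueError(f"group label must be in 1..4, got {group!r}")


def majority_vote(labels: Sequence[BinaryLabel]) -> BinaryLabel:
    """Most frequent label among an odd number of binary votes."""
    labels = [BinaryLabel(l) for l in labels]
    if len(labels) % 2 == 0:
        raise ValueError(f"majority vote needs an odd number of votes, got {len(labels)}")
    counts = Counter(labels)
    return counts.most_common(1)[0][0]


def confusion_matrix(a: Sequence, b: Sequence, labels: Sequence) -> np.ndarray:
    """Count matrix with entry (i, j) = #frames where a == labels[i] and b == labels[j]."""
    if len(a) != len(b):
        raise ValueError(f"label sequences differ in length: {len(a)} vs {len(b)}")
    index = {lab: i for i, lab in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for x, y in zip(a, b):
        m[index[x], index[y]] += 1
    return m


def cohen_kappa(matrix: np.ndarray) -> float:
    """Unweighted Cohen's kappa of a square count matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement
    (trace / total) and p_e the chance agreement from the marginals.
    A fully concordant degenerate table (all mass on one diagonal cell)
    returns 1; any other table with p_e == 1 has no defined kappa.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"kappa needs a square matrix, got shape {m.shape}")
    if (m < 0).any():
        raise ValueError("count matrix entries must be non-negative")
    total = m.sum()
    if total == 0:
        raise ValueError("kappa is undefined for an empty count matrix")
    p_o = np.trace(m) / total
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("kappa undefined: both raters used a single category but disagree")
    return float((p_o - p_e) / (1.0 - p_e))


#: Landis–Koch verbal bands, right-closed; the top band is called "Perfect"
#: (rather than "Almost perfect") following common usage in the US IQA
#: literature.
_KAPPA_BANDS = (
    (0.20, "Slight"),
    (0.40, "Fair"),
    (0.60, "Moderate"),
    (0.80, "Substantial"),
    (1.00, "Perfect"),
)


def interpret_kappa(kappa: float) -> str:
    """Verbal agreement category of a kappa value in [-1, 1]."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0:
        return "Poor"
    for upper, name in _KAPPA_BANDS:
        if kappa <= upper:
            return name
    raise AssertionError("unreachable")  # pragma: no cover


def group_size_summary(triples: Iterable[AnnotationTriple]) -> dict[int, int]:
    """Number of frames per group label; absent groups appear with count 0."""
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    for t in triples:
        counts[assign_group(t)] += 1
    return counts


def discordant_fraction(group_sizes: dict[int, int]) -> float:
    """Fraction of frames the experts disagreed on (groups 2 and 3)."""
    total = sum(group_sizes.values())
    if total == 0:
        raise ValueError("no frames")
    return (group_sizes.get(2, 0) + group_sizes.get(3, 0)) / total


def agreement_report(a: Sequence[BinaryLabel], b: Sequence[BinaryLabel]) -> AgreementReport:
    """Confusion matrix, kappa and category for two binary labelings."""
    m = confusion_matrix(a, b, labels=[NO_OK, OK])
    k = cohen_kappa(m)
    return AgreementReport(confusion=m, kappa=k, category=interpret_kappa(k))
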