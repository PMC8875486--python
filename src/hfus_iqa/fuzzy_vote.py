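"""Mamdani fuzzy-inference voting over three per-expert classifier scores.

Three binary classifiers (one trained per expert annotation column) each emit
a predicted probability that a frame is 'ok'.  Instead of crisp majority
voting, the three scores are fused by a Mamdani fuzzy inference system (FIS):

1. each input score is fuzzified against shared input sets (``low``/``high``);
2. each rule's strength is the minimum of its antecedent degrees (AND = min);
3. the rule's consequent output set is clipped at the strength (implication =
   min) and all clipped sets are aggregated pointwise (aggregation = max);
4. the crisp output is the centroid of the aggregated set on a uniform grid.

The scalar output doubles as a confidence measure: uniform thresholds at
0.25 / 0.5 / 0.75 convert it into the binary decision and into the 4-level
group label, and its distance from 0.5 grades how 'definite' the decision is.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .label_fusion import OK, NO_OK, BinaryLabel

__all__ = [
    "MembershipFunction",
    "FisSpec",
    "fuzzify",
    "fis_output",
    "threshold_binary",
    "map_output_to_group",
    "confidence_from_output",
    "output_histogram",
    "default_binary_spec",
    "default_four_class_spec",
]

#: Number of grid points used for centroid defuzzification.
DEFUZZ_GRID_POINTS = 1001

#: Uniform thresholds separating the four output bins.
THRESHOLDS = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class MembershipFunction:
    """Triangular or trapezoidal fuzzy set over [0, 1].

    ``breakpoints`` are the non-decreasing abscissae (3 for a triangle,
    4 for a trapezoid); membership is piecewise linear, 1 on the plateau
    (or apex) and 0 outside the support.  Degenerate zero-width edges
    (e.g. a trapezoid starting at its plateau, ``(0, 0, 0.2, 0.55)``)
    are allowed and evaluate to 1 at the shared breakpoint.
    """

    kind: str
    breakpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("triangular", "trapezoidal"):
            raise ValueError(f"unknown membership kind {self.kind!r}")
        n_expected = 3 if self.kind == "triangular" else 4
        if len(self.breakpoints) != n_expected:
            raise ValueError(
                f"{self.kind} membership needs {n_expected} breakpoints, got {len(self.breakpoints)}"
            )
        bp = self.breakpoints
        if any(b2 < b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError(f"breakpoints must be non-decreasing, got {bp}")
        if bp[0] < 0 or bp[-1] > 1:
            raise ValueError(f"breakpoints must lie in [0, 1], got {bp}")

    def __call__(self, x):
        return fuzzify(x, self)


def _edge(x: np.ndarray, a: float, b: float, rising: bool) -> np.ndarray:
    """Linear edge from (a, 0|1) to (b, 1|0); a step when a == b."""
    if b == a:
        return np.where(x >= a if rising else x <= a, 1.0, 0.0)
    t = (x - a) / (b - a)
    return np.clip(t if rising else 1.0 - t, 0.0, 1.0)


def fuzzify(x, mf: MembershipFunction):
    """Membership degree(s) of ``x`` in ``mf``; ``x`` must lie in [0, 1]."""
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"fuzzify input must lie in [0, 1], got {x}")
    bp = mf.breakpoints
    if mf.kind == "triangular":
        a, m, b = bp
        deg = np.minimum(_edge(arr, a, m, rising=True), _edge(arr, m, b, rising=False))
    else:
        a, b, c, d = bp
        deg = np.minimum(_edge(arr, a, b, rising=True), _edge(arr, c, d, rising=False))
    deg = np.where((arr < bp[0]) | (arr > bp[-1]), 0.0, deg)
    return float(deg) if np.isscalar(x) or arr.ndim == 0 else deg


@dataclass(frozen=True)
class FisSpec:
    """Declarative Mamdani system: shared input sets, output sets, rule base.

    The three inputs share one family of input sets, so a rule antecedent is
    a triple of input-set names, e.g. ``("high", "high", "low")``.  The rule
    base must be invariant under permutation of the inputs (the three expert
    models are exchangeable); this is validated at construction.
    Operators are fixed to the Mamdani convention: AND = min, implication =
    min, aggregation = max, defuzzification = centroid.
    """

    input_sets: Mapping[str, MembershipFunction]
    output_sets: Mapping[str, MembershipFunction]
    rules: tuple[tuple[tuple[str, str, str], str], ...]

    def __post_init__(self) -> None:
        rule_map: dict[tuple[str, str, str], str] = {}
        for antecedent, consequent in self.rules:
            if len(antecedent) != 3:
                raise ValueError("each rule antecedent names one set per input (3 names)")
            for name in antecedent:
                if name not in self.input_sets:
                    raise ValueError(f"rule references undeclared input set {name!r}")
            if consequent not in self.output_sets:
                raise ValueError(f"rule references undeclared output set {consequent!r}")
            rule_map[tuple(antecedent)] = consequent
        for antecedent, consequent in rule_map.items():
            for perm in itertools.permutations(antecedent):
                if rule_map.get(perm, consequent) != consequent:
                    raise ValueError(
                        f"rule base is not permutation-invariant: {antecedent} -> {consequent} "
                        f"but {perm} -> {rule_map[perm]}"
                    )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def sets(d: Mapping[str, MembershipFunction]) -> dict:
            return {
                name: {"kind": mf.kind, "breakpoints": list(mf.breakpoints)}
                for name, mf in d.items()
            }

        return {
            "input_sets": sets(self.input_sets),
            "output_sets": sets(self.output_sets),
            "rules": [
                {"if": list(antecedent), "then": consequent}
                for antecedent, consequent in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FisSpec":
        def sets(block: Mapping) -> dict[str, MembershipFunction]:
            return {
                name: MembershipFunction(s["kind"], tuple(float(b) for b in s["breakpoints"]))
                for name, s in block.items()
            }

        rules = tuple(
            (tuple(r["if"]), r["then"]) for r in d["rules"]
        )
        return cls(input_sets=sets(d["input_sets"]), output_sets=sets(d["output_sets"]), rules=rules)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FisSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def fis_output(scores: Sequence[float], spec: FisSpec, grid_points: int = DEFUZZ_GRID_POINTS) -> float:
    """Crisp Mamdani output in [0, 1] for a triple of 'ok' probabilities.

    Centroid defuzzification on a uniform grid of ``grid_points`` >= 1001
    points; an everywhere-zero aggregated set returns the neutral 0.5.
    """
    s = tuple(float(v) for v in scores)
    if len(s) != 3:
        raise ValueError(f"the FIS takes exactly 3 scores, got {len(s)}")
    for v in s:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"scores must lie in [0, 1], got {v}")
    if grid_points < 1001:
        raise ValueError("defuzzification grid must have at least 1001 points")

    # Fuzzify each input once against every declared input set.
    degrees = {name: tuple(fuzzify(v, mf) for v in s) for name, mf in spec.input_sets.items()}

    y = np.linspace(0.0, 1.0, grid_points)
    aggregated = np.zeros_like(y)
    for antecedent, consequent in spec.rules:
        strength = min(degrees[name][i] for i, name in enumerate(antecedent))
        if strength <= 0.0:
            continue
        clipped = np.minimum(fuzzify(y, spec.output_sets[consequent]), strength)
        np.maximum(aggregated, clipped, out=aggregated)

    mass = np.trapezoid(aggregated, y)
    if mass <= 0.0:
        return 0.5
    return float(np.trapezoid(y * aggregated, y) / mass)


def threshold_binary(y: float) -> BinaryLabel:
    """Binary decision at the 0.5 boundary; the boundary itself is 'ok'."""
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"FIS output must lie in [0, 1], got {y}")
    return OK if y >= 0.5 else NO_OK


def map_output_to_group(y: float) -> int:
    """Uniform thresholding of the FIS output into the 4-level group label.

    y < 0.25 -> 1, [0.25, 0.5) -> 3, [0.5, 0.75] -> 2, > 0.75 -> 4.
    The bins around 0.5 are half-open so that 0.5 lands on the 'ok'-side
    label (2), consistent with :func:`threshold_binary`.
    """
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"FIS output must lie in [0, 1], got {y}")
    if y < 0.25:
        return 1
    if y < 0.5:
        return 3
    if y <= 0.75:
        return 2
    return 4


def confidence_from_output(y: float) -> float:
    """Decision confidence 2*|y - 0.5|: 1 at the extremes, 0 at the boundary."""
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"FIS output must lie in [0, 1], got {y}")
    return 2.0 * abs(y - 0.5)


def output_histogram(
    outputs: Sequence[float], groups: Sequence[int], bins: int = 20
) -> dict[int, np.ndarray]:
    """Per-group histograms of FIS outputs over [0, 1]; counts sum to group sizes."""
    outputs = np.asarray(outputs, dtype=float)
    groups = np.asarray(groups)
    if outputs.shape[0] != groups.shape[0]:
        raise ValueError(
            f"outputs and groups differ in length: {outputs.shape[0]} vs {groups.shape[0]}"
        )
    edges = np.linspace(0.0, 1.0, bins + 1)
    result: dict[int, np.ndarray] = {}
    for g in (1, 2, 3, 4):
        counts, _ = np.histogram(outputs[groups == g], bins=edges)
        result[g] = counts
    return result


# -- default systems ------------------------------------------------------
#
# The input universe is covered by two overlapping trapezoids meeting at 0.5
# (so every score has positive membership somewhere and the output is
# monotone in each score).  The four output triangles are centred on the
# mid-points of the four uniform-threshold bins.  The rule base is symmetric
# in the three inputs and keyed on the count of "high" scores, so for crisp
# 0/1 scores the thresholded decision reproduces majority voting.

_INPUT_SETS = {
    "low": MembershipFunction("trapezoidal", (0.0, 0.0, 0.2, 0.55)),
    "high": MembershipFunction("trapezoidal", (0.45, 0.8, 1.0, 1.0)),
}

_OUTPUT_SETS = {
    "rejected": MembershipFunction("triangular", (0.0, 0.125, 0.25)),
    "doubtful": MembershipFunction("triangular", (0.25, 0.375, 0.5)),
    "acceptable": MembershipFunction("triangular", (0.5, 0.625, 0.75)),
    "confident": MembershipFunction("triangular", (0.75, 0.875, 1.0)),
}

_BY_HIGH_COUNT = ("rejected", "doubtful", "acceptable", "confident")


def _count_rules(output_names: Sequence[str]) -> tuple:
    rules = []
    for combo in itertools.product(("low", "high"), repeat=3):
        n_high = sum(1 for c in combo if c == "high")
        rules.append((combo, output_names[n_high]))
    return tuple(rules)


def load_shipped_spec(variant: str) -> FisSpec:
    """Load one of the two YAML specs shipped with the package.

    ``variant`` is ``"binary"`` or ``"four_class"``; the files mirror
    :func:`default_binary_spec` / :func:`default_four_class_spec` and serve
    as editable starting points for custom systems.
    """
    from importlib import resources

    if variant not in ("binary", "four_class"):
        raise ValueError(f"variant must be 'binary' or 'four_class', got {variant!r}")
    text = resources.files("hfus_iqa").joinpath(f"data/fis_{variant}.yaml").read_text()
    return FisSpec.from_dict(yaml.safe_load(text))


def default_binary_spec() -> FisSpec:
    """Default FIS for the binary voting step (decision at the 0.5 threshold)."""
    return FisSpec(_INPUT_SETS, _OUTPUT_SETS, _count_rules(_BY_HIGH_COUNT))


def default_four_class_spec() -> FisSpec:
    """Default FIS for the 4-group voting step (uniform 0.25/0.5/0.75 bins).

    Shares the structure of the binary system; only the consequent mapping is
    its own (here identical by default, the count of 'high' scores mirrors
    the count of 'ok' votes in the group definition).  Both are configurable
    from YAML.
    """
    return FisSpec(_INPUT_SETS, _OUTPUT_SETS, _count_rules(_BY_HIGH_COUNT))
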