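"""Mamdani fuzzy voting: membership functions, inference, thresholding."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hfus_iqa import (
    OK,
    NO_OK,
    FisSpec,
    MembershipFunction,
    assign_group,
    confidence_from_output,
    default_binary_spec,
    default_four_class_spec,
    fis_output,
    fuzzify,
    majority_vote,
    map_output_to_group,
    output_histogram,
    threshold_binary,
)
from hfus_iqa.fuzzy_vote import load_shipped_spec


class TestMembership:
    def test_plateau_support_and_interpolation(self):
        trap = MembershipFunction("trapezoidal", (0.1, 0.3, 0.6, 0.9))
        assert fuzzify(0.45, trap) == 1.0  # plateau
        assert fuzzify(0.05, trap) == 0.0  # outside support
        assert fuzzify(0.95, trap) == 0.0
        assert fuzzify(0.2, trap) == pytest.approx(0.5)
        tri = MembershipFunction("triangular", (0.0, 0.5, 1.0))
        assert fuzzify(0.25, tri) == pytest.approx(0.5)

    def test_degenerate_edges(self):
        trap = MembershipFunction("trapezoidal", (0.0, 0.0, 0.2, 0.55))
        assert fuzzify(0.0, trap) == 1.0
        tri = MembershipFunction("triangular", (0.75, 0.875, 1.0))
        assert fuzzify(1.0, tri) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            MembershipFunction("triangular", (0.5, 0.3, 0.9))  # decreasing
        with pytest.raises(ValueError):
            MembershipFunction("trapezoidal", (0.0, 0.5, 1.0))  # wrong arity
        with pytest.raises(ValueError):
            fuzzify(1.2, MembershipFunction("triangular", (0, 0.5, 1)))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4), st.floats(0, 1))
    def test_degree_in_unit_interval(self, bps, x):
        mf = MembershipFunction("trapezoidal", tuple(sorted(bps)))
        d = fuzzify(x, mf)
        assert 0.0 <= d <= 1.0
        if x < mf.breakpoints[0] or x > mf.breakpoints[-1]:
            assert d == 0.0


def _random_symmetric_spec(rng):
    """A random permutation-invariant spec keyed on the count of 'high' inputs."""
    def trap():
        return MembershipFunction("trapezoidal", tuple(sorted(rng.uniform(0, 1, 4))))

    def tri():
        return MembershipFunction("triangular", tuple(sorted(rng.uniform(0, 1, 3))))

    inputs = {"low": trap(), "high": trap()}
    outputs = {f"o{i}": (tri() if rng.uniform() < 0.5 else trap()) for i in range(4)}
    names = list(outputs)
    rules = []
    consequent_by_count = [names[int(rng.integers(4))] for _ in range(4)]
    for combo in itertools.product(("low", "high"), repeat=3):
        rules.append((combo, consequent_by_count[sum(c == "high" for c in combo)]))
    return FisSpec(inputs, outputs, tuple(rules))


def _oracle_centroid(scores, spec, n_grid=100_000):
    """Independent Mamdani evaluation: Riemann-sum centroid on a fine grid."""
    y = np.linspace(0.0, 1.0, n_grid)

    def mu(v, mf):
        bp = mf.breakpoints
        if mf.kind == "triangular":
            a, m, b = bp
            up = np.where(m > a, (v - a) / max(m - a, 1e-300), (v >= a).astype(float))
            down = np.where(b > m, (b - v) / max(b - m, 1e-300), (v <= b).astype(float))
        else:
            a, b2, c, d = bp
            up = np.where(b2 > a, (v - a) / max(b2 - a, 1e-300), (v >= a).astype(float))
            down = np.where(d > c, (d - v) / max(d - c, 1e-300), (v <= d).astype(float))
        deg = np.clip(np.minimum(up, down), 0, 1)
        return np.where((v < bp[0]) | (v > bp[-1]), 0.0, deg)

    agg = np.zeros_like(y)
    for antecedent, consequent in spec.rules:
        strength = min(
            float(mu(np.array([scores[i]]), spec.input_sets[name])[0])
            for i, name in enumerate(antecedent)
        )
        agg = np.maximum(agg, np.minimum(mu(y, spec.output_sets[consequent]), strength))
    mass = agg.sum()
    if mass == 0:
        return 0.5
    return float((y * agg).sum() / mass)


class TestFisOutput:
    def test_range_and_neutral_fallback(self):
        spec = default_binary_spec()
        # exactly 0.5 has positive membership in both default input sets
        assert 0.0 <= fis_output((0.5, 0.5, 0.5), spec) <= 1.0
        assert fis_output((0.5, 0.5, 0.5), spec) == pytest.approx(0.5, abs=1e-6)

    def test_permutation_invariance(self):
        spec = default_binary_spec()
        rng = np.random.default_rng(3)
        for _ in range(25):
            s = rng.uniform(0, 1, 3)
            outs = {fis_output(tuple(s[list(p)]), spec) for p in itertools.permutations(range(3))}
            assert max(outs) - min(outs) < 1e-12

    def test_monotone_in_each_coordinate(self):
        """Non-decreasing along every axis of an 11^3 grid of score triples."""
        spec = default_binary_spec()
        grid = np.linspace(0, 1, 11)
        vals = np.empty((11, 11, 11))
        for i, j, k in itertools.product(range(11), repeat=3):
            vals[i, j, k] = fis_output((grid[i], grid[j], grid[k]), spec)
        for axis in range(3):
            assert (np.diff(vals, axis=axis) >= -1e-9).all()

    def test_centroid_matches_fine_grid_oracle(self):
        """Centroid defuzzification vs an independent 1e5-point integration."""
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(40):
            spec = _random_symmetric_spec(rng)
            for _ in range(3):
                s = tuple(rng.uniform(0, 1, 3))
                assert fis_output(s, spec) == pytest.approx(_oracle_centroid(s, spec), abs=1e-3)
                checked += 1
        assert checked >= 100

    def test_extreme_inputs_map_to_extreme_groups(self):
        spec = default_four_class_spec()
        assert map_output_to_group(fis_output((1, 1, 1), spec)) == 4
        assert map_output_to_group(fis_output((0, 0, 0), spec)) == 1

    def test_crisp_inputs_reproduce_vote_fusion(self):
        """For 0/1 scores the FIS matches majority voting and group fusion."""
        b_spec, g_spec = default_binary_spec(), default_four_class_spec()
        for bits in itertools.product([0.0, 1.0], repeat=3):
            votes = [OK if b == 1.0 else NO_OK for b in bits]
            assert threshold_binary(fis_output(bits, b_spec)) == majority_vote(votes)
            assert map_output_to_group(fis_output(bits, g_spec)) == assign_group(votes)

    def test_undeclared_set_rejected(self):
        spec = default_binary_spec()
        with pytest.raises(ValueError, match="undeclared"):
            FisSpec(spec.input_sets, spec.output_sets, ((("low", "low", "nope"), "rejected"),))

    def test_asymmetric_rule_base_rejected(self):
        spec = default_binary_spec()
        rules = ((("low", "low", "high"), "rejected"), (("high", "low", "low"), "confident"))
        with pytest.raises(ValueError, match="permutation"):
            FisSpec(spec.input_sets, spec.output_sets, rules)

    def test_score_validation(self):
        spec = default_binary_spec()
        with pytest.raises(ValueError):
            fis_output((0.5, 0.5), spec)
        with pytest.raises(ValueError):
            fis_output((0.5, 0.5, 1.5), spec)


class TestThresholding:
    def test_binary_decision(self):
        assert threshold_binary(0.9) is OK
        assert threshold_binary(0.1) is NO_OK
        assert threshold_binary(0.5) is OK  # boundary assigned upward

    @pytest.mark.parametrize("y,group", [(0.10, 1), (0.30, 3), (0.60, 2), (0.90, 4),
                                         (0.25, 3), (0.5, 2), (0.75, 2)])
    def test_group_bins(self, y, group):
        assert map_output_to_group(y) == group

    def test_bins_exhaustive_and_consistent_with_binary(self):
        """Every output gets a group, and groups {2,4} <-> ok, {1,3} <-> no_ok."""
        from hfus_iqa import group_to_binary

        for y in np.linspace(0, 1, 2001):
            g = map_output_to_group(float(y))
            assert g in (1, 2, 3, 4)
            assert group_to_binary(g) == threshold_binary(float(y))

    def test_confidence(self):
        assert confidence_from_output(1.0) == 1.0
        assert confidence_from_output(0.5) == 0.0
        assert confidence_from_output(0.75) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            confidence_from_output(-0.1)


class TestHistogram:
    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        outputs = rng.uniform(0, 1, 200)
        groups = rng.integers(1, 5, 200)
        hist = output_histogram(outputs, groups, bins=10)
        for g in (1, 2, 3, 4):
            assert hist[g].sum() == (groups == g).sum()

    def test_single_full_bin(self):
        hist = output_histogram([1.0] * 5, [4] * 5, bins=4)
        assert hist[4].tolist() == [0, 0, 0, 5]
        assert hist[1].sum() == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            output_histogram([0.5], [1, 2])


class TestSerialization:
    def test_yaml_round_trip(self, tmp_path):
        spec = default_four_class_spec()
        spec.to_yaml(tmp_path / "fis.yaml")
        loaded = FisSpec.from_yaml(tmp_path / "fis.yaml")
        assert loaded == spec

    def test_shipped_specs_match_defaults(self):
        assert load_shipped_spec("binary") == default_binary_spec()
        assert load_shipped_spec("four_class") == default_four_class_spec()
        with pytest.raises(ValueError):
            load_shipped_spec("ternary")
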