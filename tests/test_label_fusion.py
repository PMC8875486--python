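"""Label fusion, majority voting and agreement statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

from hfus_iqa import (
    OK,
    NO_OK,
    AnnotationTriple,
    agreement_report,
    assign_group,
    cohen_kappa,
    confusion_matrix,
    discordant_fraction,
    group_size_summary,
    group_to_binary,
    interpret_kappa,
    majority_vote,
)

ALL_TRIPLES = [AnnotationTriple(t) for t in itertools.product([OK, NO_OK], repeat=3)]


class TestGroupAssignment:
    @pytest.mark.parametrize(
        "labels,group",
        [
            ((NO_OK, NO_OK, NO_OK), 1),
            ((OK, NO_OK, OK), 2),
            ((NO_OK, OK, NO_OK), 3),
            ((OK, OK, OK), 4),
        ],
    )
    def test_group_by_no_ok_count(self, labels, group):
        assert assign_group(AnnotationTriple(labels)) == group

    def test_preimage_sizes_over_all_combinations(self):
        """Groups 1..4 collect exactly 1, 3, 3, 1 of the 8 vote combinations."""
        counts = group_size_summary(ALL_TRIPLES)
        assert counts == {1: 1, 2: 3, 3: 3, 4: 1}

    def test_group_to_binary_matches_majority_vote_everywhere(self):
        for t in ALL_TRIPLES:
            assert group_to_binary(assign_group(t)) == majority_vote(t.labels)

    def test_group_to_binary_values(self):
        assert group_to_binary(4) is OK
        assert group_to_binary(2) is OK
        assert group_to_binary(3) is NO_OK
        assert group_to_binary(1) is NO_OK
        with pytest.raises(ValueError):
            group_to_binary(5)

    def test_majority_vote_rejects_even_input(self):
        with pytest.raises(ValueError, match="odd"):
            majority_vote([OK, NO_OK])

    def test_triple_must_have_three_labels(self):
        with pytest.raises(ValueError):
            AnnotationTriple((OK, OK))


class TestConfusionMatrix:
    def test_identity_and_off_diagonal(self):
        m = confusion_matrix([OK, NO_OK], [OK, NO_OK], labels=[NO_OK, OK])
        assert (m == np.eye(2)).all()
        m = confusion_matrix([OK, OK], [NO_OK, NO_OK], labels=[NO_OK, OK])
        assert np.trace(m) == 0 and m.sum() == 2

    def test_against_hand_count_on_random_pairs(self):
        rng = np.random.default_rng(0)
        a = [OK if v else NO_OK for v in rng.integers(0, 2, 100)]
        b = [OK if v else NO_OK for v in rng.integers(0, 2, 100)]
        m = confusion_matrix(a, b, labels=[NO_OK, OK])
        for i, la in enumerate([NO_OK, OK]):
            for j, lb in enumerate([NO_OK, OK]):
                assert m[i, j] == sum(1 for x, y in zip(a, b) if x == la and y == lb)
        assert m.sum() == 100

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            confusion_matrix([OK], [OK, OK], labels=[NO_OK, OK])


class TestCohenKappa:
    def test_known_values(self):
        assert cohen_kappa(np.diag([50, 50])) == 1.0
        assert cohen_kappa(np.array([[40, 10], [5, 45]])) == pytest.approx(0.70, abs=1e-12)
        assert cohen_kappa(np.full((2, 2), 25)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_oracle_on_random_matrices(self):
        """Matrix-form kappa equals sklearn's sequence-form kappa to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            size = int(rng.integers(2, 5))
            m = rng.integers(0, 50, size=(size, size))
            m += np.eye(size, dtype=np.int64)  # avoid degenerate single-category tables
            y1, y2 = [], []
            for i in range(size):
                for j in range(size):
                    y1 += [i] * int(m[i, j])
                    y2 += [j] * int(m[i, j])
            assert cohen_kappa(m) == pytest.approx(cohen_kappa_score(y1, y2), abs=1e-12)

    def test_invariances(self):
        rng = np.random.default_rng(1)
        m = rng.integers(1, 30, size=(3, 3))
        assert cohen_kappa(m) == pytest.approx(cohen_kappa(m.T), abs=1e-12)
        assert cohen_kappa(m * 7) == pytest.approx(cohen_kappa(m), abs=1e-12)
        assert cohen_kappa(np.diag([3, 1, 9])) == 1.0

    def test_degenerate_tables(self):
        # all mass on one diagonal cell: full agreement
        assert cohen_kappa(np.array([[10, 0], [0, 0]])) == 1.0
        # each rater stuck on a different single category: chance level
        assert cohen_kappa(np.array([[0, 10], [0, 0]])) == 0.0
        with pytest.raises(ValueError):
            cohen_kappa(np.zeros((2, 2)))


class TestKappaInterpretation:
    @pytest.mark.parametrize(
        "kappa,category",
        [(0.8322, "Perfect"), (0.7822, "Substantial"), (0.7193, "Substantial"),
         (0.9177, "Perfect"), (-0.2, "Poor"), (0.0, "Slight"), (0.20, "Slight"),
         (0.3, "Fair"), (0.60, "Moderate"), (0.80, "Substantial"), (1.0, "Perfect")],
    )
    def test_bands(self, kappa, category):
        assert interpret_kappa(kappa) == category

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.floats(min_value=-1, max_value=1, allow_nan=False))
    def test_total_monotone_step_function(self, k):
        order = ["Poor", "Slight", "Fair", "Moderate", "Substantial", "Perfect"]
        cat = interpret_kappa(k)
        assert cat in order
        eps = 1e-6
        if k + eps <= 1:
            assert order.index(interpret_kappa(k + eps)) >= order.index(cat)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.5)


class TestSummaries:
    def test_unanimous_summary(self):
        triples = [AnnotationTriple((OK, OK, OK))] * 10
        assert group_size_summary(triples) == {1: 0, 2: 0, 3: 0, 4: 10}

    def test_discordant_fraction(self):
        sizes = {1: 40, 2: 5, 3: 10, 4: 45}
        assert discordant_fraction(sizes) == pytest.approx(0.15)

    def test_agreement_report_perfect(self):
        labels = [OK, NO_OK, OK, OK]
        rep = agreement_report(labels, labels)
        assert rep.kappa == 1.0 and rep.category == "Perfect"
        assert rep.confusion.sum() == 4
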