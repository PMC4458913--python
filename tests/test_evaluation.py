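"""ROC machinery, overlap measures and the drug/category evaluation procedures."""

from __future__ import annotations

import math

import numpy as np
import pytest

from diseasome.evaluation import (
    EvaluationDataset,
    UndefinedAUCError,
    auc_from_labels,
    category_coherence,
    drug_sharing_auc,
    merge_profiles,
    per_query_retrieval_auc,
    phenotype_overlap,
    roc_auc,
    shared_drug_pairs,
)
from diseasome.scoring import DiseaseProfile
from diseasome.similarity import SimilarityMatrix

from conftest import make_ontology


def pair_comparison_auc(scores, labels):
    """Exhaustive positive-negative comparison oracle with tie-halving."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def square(ids, values):
    return SimilarityMatrix(tuple(ids), tuple(ids), np.array(values, dtype=float))


class TestRocAuc:
    def test_perfect_separation(self):
        r = auc_from_labels([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert r.auc == 1.0

    def test_worked_interleaved_example(self):
        r = auc_from_labels([0.9, 0.4, 0.7, 0.2], [True, True, False, False])
        assert r.auc == pytest.approx(0.75)
        assert r.sigma == pytest.approx(math.sqrt(0.1875 / 2), abs=1e-9)
        assert r.m == 2 and r.n == 2

    def test_all_tied_scores_give_half(self):
        r = auc_from_labels([0.5] * 6, [True, False, True, False, False, False])
        assert r.auc == pytest.approx(0.5)

    def test_curve_endpoints_monotone_and_area(self):
        rng = np.random.default_rng(7)
        scores = rng.random(50).round(1)  # coarse grid forces ties
        labels = rng.random(50) < 0.4
        r = auc_from_labels(scores.tolist(), labels.tolist())
        fpr = [p[0] for p in r.curve]
        tpr = [p[1] for p in r.curve]
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert all(a <= b + 1e-12 for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(tpr, tpr[1:]))
        assert np.trapezoid(tpr, fpr) == pytest.approx(r.auc, abs=1e-9)

    def test_matches_pair_comparison_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 200))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n).tolist()
            labels = (rng.random(n) < 0.5).tolist()
            if not (any(labels) and not all(labels)):
                continue
            r = auc_from_labels(scores, labels)
            assert r.auc == pytest.approx(pair_comparison_auc(scores, labels), abs=1e-12)

    def test_reversing_scores_complements_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.random(40).tolist()
        labels = (rng.random(40) < 0.3).tolist()
        a = auc_from_labels(scores, labels).auc
        b = auc_from_labels([-s for s in scores], labels).auc
        assert a + b == pytest.approx(1.0)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(UndefinedAUCError):
            auc_from_labels([0.1, 0.2], [True, True])

    def test_roc_auc_treats_unlisted_pairs_as_negative(self):
        scores = {("g1", "d1"): 0.9, ("g1", "d2"): 0.2, ("g2", "d1"): 0.4}
        dataset = EvaluationDataset(frozenset({("g1", "d1")}), "toy")
        assert roc_auc(scores, dataset).auc == 1.0


class TestPerQueryRetrieval:
    def test_positives_on_top(self):
        m = square("abc", [[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
        r = per_query_retrieval_auc(m, {"a": {"b"}, "b": {"a"}})
        assert r.auc == 1.0

    def test_single_query_middle_rank(self):
        m = square("qxyz", [
            [1.0, 0.9, 0.5, 0.1],
            [0.9, 1.0, 0.0, 0.0],
            [0.5, 0.0, 1.0, 0.0],
            [0.1, 0.0, 0.0, 1.0],
        ])
        r = per_query_retrieval_auc(m, {"q": {"y"}})
        assert r.auc == pytest.approx(0.5)

    def test_all_identical_similarities_give_half(self):
        m = square("abc", np.ones((3, 3)))
        assert per_query_retrieval_auc(m, {"a": {"b"}}).auc == pytest.approx(0.5)

    def test_query_never_its_own_target(self):
        m = square("abc", [[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
        # query a scores (a, b) and (a, c) only; the unit self-similarity
        # (a, a) never enters the pool, and query b (no positives) is skipped
        r = per_query_retrieval_auc(m, {"a": {"b"}, "b": set()})
        assert (r.m, r.n) == (1, 1)
        assert r.auc == 1.0


class TestCategoryCoherence:
    def planted_matrix(self, rng=None):
        # two 4-disease blocks, high within, low between
        ids = [f"d{i}" for i in range(8)]
        values = np.full((8, 8), 0.1)
        values[:4, :4] = 0.9
        values[4:, 4:] = 0.9
        np.fill_diagonal(values, 1.0)
        return square(ids, values)

    def test_separated_blocks_score_one(self):
        m = self.planted_matrix()
        cats = {f"d{i}": {"C1" if i < 4 else "C2"} for i in range(8)}
        result = category_coherence(m, cats)
        assert result["C1"].auc == 1.0 and result["C2"].auc == 1.0

    def test_shuffled_categories_near_half(self):
        rng = np.random.default_rng(5)
        m = self.planted_matrix()
        aucs = []
        for _ in range(100):
            labels = rng.permutation(["C1"] * 4 + ["C2"] * 4)
            cats = {f"d{i}": {labels[i]} for i in range(8)}
            result = category_coherence(m, cats)
            aucs.extend(r.auc for r in result.values())
        assert abs(float(np.mean(aucs)) - 0.5) < 0.05

    def test_multi_category_disease_counts_for_both(self):
        m = self.planted_matrix()
        cats = {f"d{i}": {"C1"} for i in range(4)}
        cats.update({f"d{i}": {"C2"} for i in range(4, 8)})
        cats["d0"] = {"C1", "C2"}
        result = category_coherence(m, cats)
        assert result["C2"].m > category_coherence(
            m, {**cats, "d0": {"C1"}}
        )["C2"].m

    def test_tiny_category_skipped_with_warning(self):
        m = self.planted_matrix()
        cats = {f"d{i}": {"C1"} for i in range(8)}
        cats["d0"] = {"C1", "LONELY"}
        with pytest.warns(UserWarning, match="LONELY"):
            result = category_coherence(m, cats)
        assert "LONELY" not in result


class TestOverlap:
    def test_identical_sets(self, diamond):
        r = phenotype_overlap({"A", "B"}, {"A", "B"}, diamond)
        assert r.jaccard == 1.0 and r.coverage == 1.0

    def test_hand_counted_overlap(self, diamond):
        ont = make_ontology({c: set() for c in "abcd"})
        r = phenotype_overlap({"a", "b", "c"}, {"b", "c", "d"}, ont)
        assert r.jaccard == pytest.approx(0.5)
        assert r.coverage == pytest.approx(2 / 3)

    def test_closure_connects_disjoint_leaves(self, diamond):
        open_r = phenotype_overlap({"A"}, {"B"}, diamond, closed=False)
        closed_r = phenotype_overlap({"A"}, {"B"}, diamond, closed=True)
        assert open_r.jaccard == 0.0
        assert closed_r.jaccard > 0.0  # R is in both closures

    def test_empty_reference_rejected(self, diamond):
        with pytest.raises(ValueError):
            phenotype_overlap({"A"}, set(), diamond)


class TestDrugSharing:
    def test_single_indication_drugs_share_nothing(self):
        assert shared_drug_pairs({"x": {"A"}, "y": {"B"}}) == set()

    def test_three_way_indication_enumerates_pairs(self):
        pairs = shared_drug_pairs({"x": {"A", "B", "C"}})
        assert pairs == {frozenset("AB"), frozenset("AC"), frozenset("BC")}

    def test_duplicate_pairs_collapse(self):
        pairs = shared_drug_pairs({"x": {"A", "B"}, "y": {"A", "B"}})
        assert pairs == {frozenset("AB")}

    def test_three_disease_worked_auc(self):
        m = square("ABC", [[1.0, 0.9, 0.3], [0.9, 1.0, 0.5], [0.3, 0.5, 1.0]])
        r = drug_sharing_auc(m, {frozenset("AB")})
        assert r.auc == 1.0
        assert (r.m, r.n) == (1, 2)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(17)
        ids = [f"d{i}" for i in range(12)]
        values = (rng.random((12, 12)) + rng.random((12, 12)).T) / 2
        values = (values + values.T) / 2
        np.fill_diagonal(values, 1.0)
        m = square(ids, values)
        aucs = []
        for _ in range(100):
            chosen = rng.choice(12, size=4, replace=False)
            pairs = {
                frozenset((ids[i], ids[j]))
                for i in chosen for j in chosen if i < j
            }
            aucs.append(drug_sharing_auc(m, pairs).auc)
        assert abs(float(np.mean(aucs)) - 0.5) < 0.05


class TestMergeProfiles:
    def test_union_identity_and_commutativity(self):
        a = DiseaseProfile("d", frozenset({"x", "y"}))
        b = DiseaseProfile("d", frozenset({"y", "z"}))
        empty = DiseaseProfile("d", frozenset())
        assert merge_profiles(a, empty).phenotype_ids == a.phenotype_ids
        assert merge_profiles(a, b).phenotype_ids == {"x", "y", "z"}
        assert merge_profiles(a, b) == merge_profiles(b, a)
        assert merge_profiles(a, a) == a

    def test_mismatched_disease_rejected(self):
        with pytest.raises(ValueError):
            merge_profiles(
                DiseaseProfile("d1", frozenset({"x"})),
                DiseaseProfile("d2", frozenset({"x"})),
            )
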