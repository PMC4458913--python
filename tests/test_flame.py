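"""FLAME clustering recovery, purity arithmetic and the Rand index."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from diseasome.flame import (
    OUTLIER_LABEL,
    categories_to_partition,
    cluster_purity,
    flame_cluster,
    hard_clusters,
    rand_index,
)
from diseasome.similarity import SimilarityMatrix


def square(ids, values):
    return SimilarityMatrix(tuple(ids), tuple(ids), np.asarray(values, dtype=float))


def two_block_matrix(n_a=10, n_b=10, within=0.9, between=0.1, rng=None):
    n = n_a + n_b
    values = np.full((n, n), between)
    values[:n_a, :n_a] = within
    values[n_a:, n_a:] = within
    if rng is not None:
        jitter = rng.normal(0, 0.01, size=(n, n))
        values = values + (jitter + jitter.T) / 2
    np.fill_diagonal(values, 1.0)
    ids = [f"a{i:02d}" for i in range(n_a)] + [f"b{i:02d}" for i in range(n_b)]
    return square(ids, values), set(ids[:n_a]), set(ids[n_a:])


class TestFlame:
    def test_two_planted_blocks_recovered_exactly(self):
        m, block_a, block_b = two_block_matrix()
        result = flame_cluster(m, k=3)
        labels_a = {result.cluster_of[o] for o in block_a}
        labels_b = {result.cluster_of[o] for o in block_b}
        assert len(labels_a) == 1 and len(labels_b) == 1
        assert labels_a != labels_b
        assert not result.outliers

    def test_memberships_are_distributions(self):
        rng = np.random.default_rng(2)
        m, *_ = two_block_matrix(rng=rng)
        result = flame_cluster(m, k=4)
        sums = result.memberships.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert (result.memberships >= -1e-12).all()

    def test_uniform_similarity_collapses_to_single_cluster(self):
        n = 8
        values = np.full((n, n), 0.5)
        np.fill_diagonal(values, 1.0)
        m = square([f"o{i}" for i in range(n)], values)
        result = flame_cluster(m, k=3)
        assert result.n_clusters == 1
        assert len(result.csos) == 1
        assert set(result.cluster_of.values()) == {0}

    def test_deterministic_across_reruns(self):
        rng = np.random.default_rng(9)
        m, *_ = two_block_matrix(rng=rng)
        r1 = flame_cluster(m, k=5)
        r2 = flame_cluster(m, k=5)
        assert r1.cluster_of == r2.cluster_of
        assert np.array_equal(r1.memberships, r2.memberships)
        assert r1.csos == r2.csos

    def test_each_cluster_has_exactly_one_cso(self):
        rng = np.random.default_rng(12)
        m, *_ = two_block_matrix(n_a=12, n_b=8, rng=rng)
        result = flame_cluster(m, k=4)
        cso_labels = [result.cluster_of[c] for c in result.csos]
        assert sorted(cso_labels) == list(range(result.n_clusters))

    def test_asymmetric_matrix_rejected(self):
        values = np.eye(4)
        values[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            flame_cluster(square("abcd", values), k=2)

    def test_k_out_of_range_rejected(self):
        m, *_ = two_block_matrix(3, 3)
        with pytest.raises(ValueError, match="k must"):
            flame_cluster(m, k=6)


class TestPurity:
    def test_homogeneous_cluster(self):
        clusters = {0: {"a", "b", "c"}}
        cats = {x: {"M"} for x in "abc"}
        per, avg = cluster_purity(clusters, cats)
        assert per[0] == 1.0 and avg == 1.0

    def test_majority_by_containment(self):
        clusters = {0: {"a", "b", "c"}}
        cats = {"a": {"M"}, "b": {"M", "K"}, "c": {"K"}}
        per, _ = cluster_purity(clusters, cats)
        # both M and K are contained by 2 of 3 members; tie broken to K (name order)
        assert per[0] == pytest.approx(2 / 3)

    def test_average_is_arithmetic_mean(self):
        clusters = {0: {"a", "b"}, 1: {"c", "d"}}
        cats = {"a": {"M"}, "b": {"M"}, "c": {"M"}, "d": {"K"}}
        _, avg = cluster_purity(clusters, cats)
        assert avg == pytest.approx((1.0 + 0.5) / 2)

    def test_empty_cluster_excluded_with_warning(self):
        clusters = {0: {"a"}, 1: set()}
        with pytest.warns(UserWarning, match="empty"):
            per, _ = cluster_purity(clusters, {"a": {"M"}})
        assert 1 not in per


def oracle_rand(a, b):
    x = y = 0
    for p, q in combinations(sorted(a), 2):
        sa, sb = a[p] == a[q], b[p] == b[q]
        x += sa and sb
        y += (not sa) and (not sb)
    n = len(a)
    return (x + y) / (n * (n - 1) / 2)


class TestRandIndex:
    def test_identical_partitions(self):
        part = {"a": 0, "b": 0, "c": 1}
        assert rand_index(part, dict(part)).rand == 1.0

    def test_worked_four_object_example(self):
        a = {"a": 0, "b": 0, "c": 1, "d": 1}
        b = {"a": 0, "b": 0, "c": 0, "d": 1}
        r = rand_index(a, b)
        assert (r.same_same, r.diff_diff) == (1, 2)
        assert r.rand == pytest.approx(0.5)

    def test_two_objects_full_disagreement(self):
        assert rand_index({"a": 0, "b": 1}, {"a": 0, "b": 0}).rand == 0.0

    def test_symmetric_and_relabeling_invariant(self):
        rng = np.random.default_rng(6)
        objects = [f"o{i}" for i in range(30)]
        a = {o: int(rng.integers(4)) for o in objects}
        b = {o: int(rng.integers(3)) for o in objects}
        assert rand_index(a, b).rand == rand_index(b, a).rand
        relabeled = {o: f"cluster-{v}" for o, v in a.items()}
        assert rand_index(relabeled, b).rand == rand_index(a, b).rand

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(2, 50))
            objects = [f"o{i}" for i in range(n)]
            a = {o: int(rng.integers(1, 6)) for o in objects}
            b = {o: int(rng.integers(1, 6)) for o in objects}
            assert rand_index(a, b).rand == pytest.approx(oracle_rand(a, b))

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            rand_index({"a": 0, "b": 0}, {"a": 0, "c": 0})


class TestCategoriesToPartition:
    def test_exclude_multi_label(self):
        cats = {"a": {"X"}, "b": {"X", "Y"}, "c": {"Y"}}
        assert categories_to_partition(cats) == {"a": "X", "c": "Y"}

    def test_first_category_projection(self):
        cats = {"a": {"X"}, "b": {"Y", "X"}}
        assert categories_to_partition(cats, multi_label="first") == {"a": "X", "b": "X"}


def test_planted_blocks_give_perfect_purity_and_rand():
    m, block_a, block_b = two_block_matrix()
    result = flame_cluster(m, k=3)
    cats = {o: {"A"} for o in block_a} | {o: {"B"} for o in block_b}
    clusters = hard_clusters(result)
    _, avg_purity = cluster_purity(clusters, cats)
    assert avg_purity == 1.0
    truth = categories_to_partition(cats)
    assert rand_index(result.cluster_of, truth).rand == 1.0
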