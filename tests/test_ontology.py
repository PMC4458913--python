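"""Closure, term-set and OBO round-trip behavior of the ontology layer."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diseasome.corpus import normalize_text
from diseasome.ontology import (
    MissingClassError,
    load_obo,
    merge_ontologies,
    subclass_closure,
    superclass_closure,
    term_set,
    write_obo,
)
from diseasome.synthetic import generate_ontology

from conftest import make_ontology


def brute_force_reachable(edges: dict[str, set[str]], start: set[str],
                          forward: bool) -> set[str]:
    """Reachability oracle over the raw edge list, independent of Ontology."""
    # forward=False follows child->parent edges, True follows parent->child
    reached = set(start)
    changed = True
    while changed:
        changed = False
        for child, parents in edges.items():
            if forward:
                if (parents & reached) and child not in reached:
                    reached.add(child)
                    changed = True
            else:
                if child in reached and not parents <= reached:
                    reached |= parents
                    changed = True
    return reached


class TestClosures:
    def test_leaf_closure_is_reflexive(self, chain):
        assert subclass_closure(chain, "A1") == {"A1"}

    def test_chain_descends_transitively(self, chain):
        assert subclass_closure(chain, "R") == {"R", "A", "A1"}

    def test_diamond_counts_shared_descendant_once(self, diamond):
        assert subclass_closure(diamond, "R") == {"R", "A", "B", "C"}

    def test_root_superclass_closure_is_itself(self, diamond):
        assert superclass_closure(diamond, {"R"}) == {"R"}

    def test_chain_ancestors(self, chain):
        assert superclass_closure(chain, {"A1"}) == {"A1", "A", "R"}

    def test_diamond_ancestors_through_both_parents(self, diamond):
        assert superclass_closure(diamond, {"C"}) == {"C", "A", "B", "R"}

    def test_unknown_class_raises(self, chain):
        with pytest.raises(MissingClassError):
            subclass_closure(chain, "nope")
        with pytest.raises(MissingClassError):
            superclass_closure(chain, {"nope"})

    def test_superclass_closure_is_idempotent(self, diamond):
        once = superclass_closure(diamond, {"C", "A"})
        assert superclass_closure(diamond, once) == once


@st.composite
def random_dag(draw):
    """A child->parents mapping over n classes where parents precede children."""
    n = draw(st.integers(min_value=1, max_value=50))
    edges: dict[str, set[str]] = {"n0": set()}
    for i in range(1, n):
        k = draw(st.integers(min_value=0, max_value=min(3, i)))
        parents = draw(
            st.sets(st.integers(min_value=0, max_value=i - 1), min_size=k, max_size=k)
        )
        # every non-root must reach the root: force a parent when none drawn
        if not parents:
            parents = {draw(st.integers(min_value=0, max_value=i - 1))}
        edges[f"n{i}"] = {f"n{j}" for j in parents}
    return edges


@settings(max_examples=60, deadline=None, derandomize=True)
@given(random_dag(), st.randoms(use_true_random=False))
def test_closures_match_reachability_oracle(edges, rnd):
    ontology = make_ontology(edges)
    cid = rnd.choice(sorted(edges))
    assert subclass_closure(ontology, cid) == brute_force_reachable(edges, {cid}, True)
    assert superclass_closure(ontology, {cid}) == brute_force_reachable(edges, {cid}, False)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(random_dag(), st.data())
def test_superclass_closure_is_monotone(edges, data):
    ontology = make_ontology(edges)
    ids = sorted(edges)
    y = set(data.draw(st.sets(st.sampled_from(ids), min_size=1)))
    x = set(data.draw(st.sets(st.sampled_from(sorted(y)), min_size=1)))
    assert superclass_closure(ontology, x) <= superclass_closure(ontology, y)


class TestTermSets:
    def test_single_label_leaf(self):
        ont = make_ontology({"X": set()}, labels={"X": "vitiligo"})
        assert term_set(ont, "X", normalize_text).terms == {("vitiligo",)}

    def test_synonym_equal_to_label_collapses(self):
        ont = make_ontology(
            {"X": set()}, labels={"X": "Vitiligo"}, synonyms={"X": {"vitiligo"}}
        )
        assert term_set(ont, "X", normalize_text).terms == {("vitiligo",)}

    def test_parent_term_set_includes_child_labels(self):
        ont = make_ontology(
            {"P": set(), "C": {"P"}},
            labels={"P": "alopecia", "C": "alopecia areata"},
        )
        assert term_set(ont, "P", normalize_text).terms == {
            ("alopecia",),
            ("alopecia", "areata"),
        }
        assert term_set(ont, "C", normalize_text).terms == {("alopecia", "areata")}

    def test_term_set_is_superset_of_subclass_term_set(self):
        ontology = generate_ontology(3, n_classes=40, synonym_rate=0.5)
        for cid in ontology.classes:
            parent_terms = term_set(ontology, cid, normalize_text).terms
            for child in subclass_closure(ontology, cid):
                assert term_set(ontology, child, normalize_text).terms <= parent_terms


class TestOboIO:
    def test_round_trip_preserves_structure(self, tmp_path):
        original = generate_ontology(7, n_classes=30, synonym_rate=0.4)
        path = tmp_path / "onto.obo"
        write_obo(original, path)
        reread = load_obo(path)
        assert set(reread.classes) == set(original.classes)
        for cid, cls in original.classes.items():
            assert reread[cid].primary_label == cls.primary_label
            assert reread[cid].synonyms == cls.synonyms
            assert reread[cid].parent_ids == cls.parent_ids

    def test_obsolete_and_scoped_synonyms(self, tmp_path):
        text = """format-version: 1.2

[Term]
id: T:1
name: root

[Term]
id: T:2
name: child
synonym: "kid" NARROW []
is_a: T:1

[Term]
id: T:3
name: gone
is_obsolete: true
"""
        path = tmp_path / "t.obo"
        path.write_text(text)
        ont = load_obo(path)
        assert "T:3" not in ont
        assert ont["T:2"].synonyms == {"kid"}
        assert ont["T:2"].parent_ids == {"T:1"}
        assert ont.roots == {"T:1"}

    def test_merge_rejects_duplicate_ids(self, diamond):
        with pytest.raises(ValueError, match="duplicate"):
            merge_ontologies(diamond, diamond)

    def test_merge_keeps_both_hierarchies(self, diamond, chain):
        other = make_ontology({"Q": set(), "Q1": {"Q"}})
        merged = merge_ontologies(diamond, other)
        assert superclass_closure(merged, {"C"}) == {"C", "A", "B", "R"}
        assert superclass_closure(merged, {"Q1"}) == {"Q1", "Q"}


def test_cycle_detection():
    with pytest.raises(ValueError, match="cycle"):
        make_ontology({"A": {"B"}, "B": {"A"}})
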