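"""Shared fixtures: tiny hand-built ontologies and the reference synthetic bundle."""

from __future__ import annotations

import pytest

from diseasome.corpus import filter_corpus, cooccurrence_table, normalize_text
from diseasome.ontology import Ontology, OntologyClass, merge_ontologies, term_set
from diseasome.scoring import rank_all, score_table
from diseasome.synthetic import generate_bundle


def make_ontology(edges: dict[str, set[str]], labels: dict[str, str] | None = None,
                  synonyms: dict[str, set[str]] | None = None) -> Ontology:
    """Build an ontology from a child -> parents mapping."""
    labels = labels or {}
    synonyms = synonyms or {}
    return Ontology({
        cid: OntologyClass(
            id=cid,
            primary_label=labels.get(cid, f"label {cid}"),
            synonyms=frozenset(synonyms.get(cid, ())),
            parent_ids=frozenset(parents),
        )
        for cid, parents in edges.items()
    })


@pytest.fixture
def diamond():
    """R -> {A, B} -> C: the smallest DAG where a class is reached twice."""
    return make_ontology({"R": set(), "A": {"R"}, "B": {"R"}, "C": {"A", "B"}})


@pytest.fixture
def chain():
    """R -> A -> A1 chain."""
    return make_ontology({"R": set(), "A": {"R"}, "A1": {"A"}})


@pytest.fixture(scope="session")
def bundle():
    """The reference synthetic bundle: 20 diseases, 5-class signatures,
    2,000 documents, 60 model profiles at corruption 0.2."""
    return generate_bundle(1)


@pytest.fixture(scope="session")
def mined(bundle):
    """The bundle mined end-to-end: term sets, filtered corpus, ranked associations."""
    def term_sets(ontology):
        return [
            term_set(ontology, cid, normalize_text)
            for cid in sorted(ontology.classes)
            if cid not in ontology.roots
        ]

    disease_sets = term_sets(bundle.disease_ontology)
    phenotype_sets = term_sets(bundle.phenotype_ontology)
    corpus = filter_corpus(bundle.corpus, disease_sets + phenotype_sets)
    counts = cooccurrence_table(corpus, disease_sets, phenotype_sets)
    ranked = rank_all(score_table(counts))
    return {
        "merged": merge_ontologies(bundle.disease_ontology, bundle.phenotype_ontology),
        "disease_sets": disease_sets,
        "phenotype_sets": phenotype_sets,
        "corpus": corpus,
        "counts": counts,
        "ranked": ranked,
    }
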