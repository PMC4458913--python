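"""Seeded generators for toy ontologies, corpora and annotation bundles.

The generators emulate, at desk scale, the inputs of the full analysis: a
disease ontology whose leaves fall under top-level categories, a phenotype
ontology, a literature corpus in which each disease co-occurs with a
planted signature of phenotype classes over background noise, and model
(mouse genotype) annotation profiles that copy a disease's signature with a
controlled corruption rate.  Everything is a pure function of its seed:
rebuilding a bundle with the same seed is bit-identical, and the corpus,
ontology and annotation sub-generators draw from independent keyed streams
so that, e.g., enlarging the corpus does not perturb the annotations.

Class labels are pseudo-words carrying an ontology-specific marker letter,
so disease and phenotype lexicons can never collide and every text match is
unambiguous.  Default bundle parameters — 20 diseases with signatures of 5
phenotype classes, a 2,000-document corpus, 60 model profiles at corruption
0.2 — define the reference conditions under which the pipeline's
parameter-recovery properties are stated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import Document, write_corpus_tsv
from .evaluation import EvaluationDataset
from .ontology import Ontology, OntologyClass, write_obo
from .similarity import AnnotationProfile, write_profiles_tsv

__all__ = [
    "SyntheticBundle",
    "generate_ontology",
    "generate_corpus",
    "generate_annotations",
    "generate_bundle",
    "write_bundle",
]

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"

# neutral filler vocabulary; never collides with generated labels
_FILLER = (
    "study patients results measured cohort clinical observed analysis "
    "reported treatment outcome baseline followup significant association "
    "sample control group method data review case series population"
).split()


def _pseudoword(rng: np.random.Generator, tag: str, n_syllables: int = 3) -> str:
    syllables = "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syllables)
    )
    return tag + syllables


def _unique_label(rng: np.random.Generator, tag: str, used: set[str]) -> str:
    while True:
        label = f"{_pseudoword(rng, tag)} {_pseudoword(rng, tag, 2)}"
        if label not in used:
            used.add(label)
            return label


def generate_ontology(
    seed: int,
    n_classes: int,
    max_parents: int = 2,
    synonym_rate: float = 0.2,
    id_prefix: str = "SYN",
    label_tag: str = "x",
) -> Ontology:
    """Generate a rooted random DAG ontology with unique two-word labels.

    Class 0 is the root; every later class draws 1..max_parents parents
    among earlier classes, so the graph is acyclic by construction.  With
    ``max_parents=1`` the result is a tree.  ``label_tag`` is a marker
    letter prefixed to every generated word, keeping lexicons of different
    ontologies disjoint.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    rng = np.random.default_rng([seed, 11])
    used: set[str] = set()
    classes: dict[str, OntologyClass] = {}
    ids = [f"{id_prefix}:{i:04d}" for i in range(n_classes)]
    for i, cid in enumerate(ids):
        label = _unique_label(rng, label_tag, used)
        synonyms: set[str] = set()
        if rng.random() < synonym_rate:
            synonyms.add(_unique_label(rng, label_tag, used))
        if i == 0:
            parents: frozenset[str] = frozenset()
        else:
            n_par = 1 + int(rng.integers(max_parents)) if max_parents > 1 else 1
            n_par = min(n_par, i)
            parents = frozenset(
                ids[j] for j in rng.choice(i, size=n_par, replace=False)
            )
        classes[cid] = OntologyClass(
            id=cid, primary_label=label, synonyms=frozenset(synonyms), parent_ids=parents
        )
    return Ontology(classes)


def _mention(rng: np.random.Generator, ontology: Ontology, class_id: str) -> str:
    """A label or (sometimes) synonym of the class, as it would appear in text."""
    cls = ontology[class_id]
    if cls.synonyms and rng.random() < 0.3:
        return sorted(cls.synonyms)[rng.integers(len(cls.synonyms))]
    return cls.primary_label


def _filler(rng: np.random.Generator, n_words: int) -> list[str]:
    return [_FILLER[rng.integers(len(_FILLER))] for _ in range(n_words)]


def generate_corpus(
    seed: int,
    truth_profiles: dict[str, frozenset[str]],
    disease_ontology: Ontology,
    phenotype_ontology: Ontology,
    n_docs: int = 2000,
    signal_rate: float = 0.5,
    noise_rate: float = 0.2,
    comention_rate: float = 0.5,
    signature_weights: dict[str, dict[str, float]] | None = None,
) -> list[Document]:
    """Generate abstracts with planted disease–phenotype co-occurrence signal.

    A *signal* document (probability ``signal_rate``) mentions one disease
    and one phenotype from that disease's planted signature in the same
    abstract; with probability ``comention_rate`` it additionally mentions
    one of the disease's two *confusion partners* (neighbors on a ring over
    the sorted disease list), emulating the comorbidity and
    differential-diagnosis co-mentions of real abstracts.  Partner diseases
    thereby acquire genuine but weaker co-occurrences with a foreign
    signature, which is what makes over-long phenotype profiles misleading.
    ``signature_weights`` optionally biases which signature phenotype a
    signal document mentions (e.g. cardinal family-level phenotypes more
    often than distinctive ones); default is uniform.  A *noise* document
    mentions, independently, a random disease (probability ``noise_rate``)
    and a random phenotype (probability ``0.9``), so random pairs co-occur
    only at chance level.  One guaranteed signal document per planted
    (disease, phenotype) pair is emitted first, so every planted
    association is attested at least once even in tiny corpora; the
    remaining documents are drawn at the stated rates.
    """
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    rng = np.random.default_rng([seed, 23])
    diseases = sorted(truth_profiles)
    partners = {
        d: (diseases[i - 1], diseases[(i + 1) % len(diseases)])
        for i, d in enumerate(diseases)
    } if len(diseases) > 1 else {diseases[0]: ()}
    sig_dist: dict[str, tuple[list[str], np.ndarray]] = {}
    for d in diseases:
        classes = sorted(truth_profiles[d])
        if signature_weights and d in signature_weights:
            w = np.array([signature_weights[d].get(c, 1.0) for c in classes])
        else:
            w = np.ones(len(classes))
        sig_dist[d] = (classes, w / w.sum())
    phenotype_ids = sorted(
        cid for cid in phenotype_ontology.classes if phenotype_ontology[cid].parent_ids
    )
    docs: list[Document] = []

    def signal_doc(doc_id: str, disease: str, phenotype: str) -> Document:
        words = _filler(rng, 4)
        words.append(_mention(rng, disease_ontology, disease))
        words.extend(_filler(rng, 3))
        words.append(_mention(rng, phenotype_ontology, phenotype))
        words.extend(_filler(rng, 3))
        if partners[disease] and rng.random() < comention_rate:
            other = partners[disease][rng.integers(2)]
            words.append(_mention(rng, disease_ontology, other))
            words.extend(_filler(rng, 2))
        return Document(doc_id=doc_id, title=" ".join(_filler(rng, 5)),
                        abstract=" ".join(words))

    planted = [(d, p) for d in diseases for p in sorted(truth_profiles[d])]
    for d, p in planted[:n_docs]:
        docs.append(signal_doc(f"DOC:{len(docs):06d}", d, p))

    while len(docs) < n_docs:
        doc_id = f"DOC:{len(docs):06d}"
        if rng.random() < signal_rate:
            d = diseases[rng.integers(len(diseases))]
            classes, probs = sig_dist[d]
            p = classes[rng.choice(len(classes), p=probs)]
            docs.append(signal_doc(doc_id, d, p))
        else:
            words = _filler(rng, 5)
            if rng.random() < noise_rate:
                d = diseases[rng.integers(len(diseases))]
                words.append(_mention(rng, disease_ontology, d))
            words.extend(_filler(rng, 2))
            if rng.random() < 0.9:
                p = phenotype_ids[rng.integers(len(phenotype_ids))]
                words.append(_mention(rng, phenotype_ontology, p))
            words.extend(_filler(rng, 2))
            docs.append(
                Document(doc_id=doc_id, title=" ".join(_filler(rng, 5)),
                         abstract=" ".join(words))
            )
    return docs


def generate_annotations(
    seed: int,
    truth_profiles: dict[str, frozenset[str]],
    phenotype_ontology: Ontology,
    n_models: int = 60,
    positive_fraction: float = 0.8,
    corruption_rate: float = 0.2,
) -> tuple[list[AnnotationProfile], EvaluationDataset]:
    """Generate model (genotype) profiles plus the positive-pair truth table.

    Each positive model copies one disease's planted signature, replacing
    each class with probability ``corruption_rate`` by a random non-signature
    phenotype; diseases are cycled so positives spread evenly.  Negative
    models draw entirely random phenotype sets of the same size.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng([seed, 37])
    diseases = sorted(truth_profiles)
    pool = sorted(
        cid for cid in phenotype_ontology.classes if phenotype_ontology[cid].parent_ids
    )
    n_pos = round(n_models * positive_fraction)
    profiles: list[AnnotationProfile] = []
    positives: set[tuple[str, str]] = set()

    def random_class(exclude: set[str]) -> str:
        while True:
            c = pool[rng.integers(len(pool))]
            if c not in exclude:
                return c

    for m in range(n_models):
        model_id = f"MODEL:{m:04d}"
        if m < n_pos:
            disease = diseases[m % len(diseases)]
            signature = sorted(truth_profiles[disease])
            phen: set[str] = set()
            for cls in signature:
                if rng.random() < corruption_rate:
                    # replacements are drawn outside the signature so the
                    # corruption rate exactly controls the realized overlap
                    # with the truth (a replacement never restores it)
                    phen.add(random_class(set(signature) | phen))
                else:
                    phen.add(cls)
            positives.add((model_id, disease))
        else:
            size = len(truth_profiles[diseases[0]])
            phen = set()
            while len(phen) < size:
                phen.add(pool[rng.integers(len(pool))])
        profiles.append(
            AnnotationProfile(entity_id=model_id, phenotype_ids=frozenset(phen),
                              entity_kind="genotype")
        )
    return profiles, EvaluationDataset(positives=frozenset(positives), name="synthetic")


@dataclass(frozen=True)
class SyntheticBundle:
    """A complete reproducible toy input set for the end-to-end pipeline."""

    disease_ontology: Ontology
    phenotype_ontology: Ontology
    corpus: list[Document]
    truth_profiles: dict[str, frozenset[str]]
    model_profiles: list[AnnotationProfile]
    eval_positives: EvaluationDataset
    categories: dict[str, set[str]]
    seed: int


def generate_bundle(
    seed: int,
    n_diseases: int = 20,
    signature_size: int = 5,
    n_phenotype_classes: int = 140,
    n_categories: int = 4,
    n_docs: int = 2000,
    signal_rate: float = 0.5,
    noise_rate: float = 0.2,
    comention_rate: float = 0.5,
    cardinal_weight: float = 3.0,
    n_models: int = 60,
    positive_fraction: float = 0.8,
    corruption_rate: float = 0.2,
) -> SyntheticBundle:
    """Build the full synthetic input bundle from one seed.

    The disease ontology is root → categories → disease leaves, each leaf
    under exactly one category.  Planted phenotype signatures mimic disease
    families: neighboring diseases on a ring share one *cardinal* phenotype
    with each neighbor (mentioned ``cardinal_weight`` times more often in
    signal documents), while the remaining signature classes are unique to
    the disease and carry its distinctive signal.  With fewer than three
    diseases, or signatures smaller than three classes, signatures are
    simply disjoint.
    """
    shared_scheme = n_diseases >= 3 and signature_size >= 3
    needed = (
        n_diseases * (signature_size - 1) if shared_scheme
        else n_diseases * signature_size
    )
    if n_phenotype_classes <= needed:
        raise ValueError(
            f"need more than {needed} phenotype classes for the planted signatures"
        )
    rng = np.random.default_rng([seed, 5])

    # disease ontology: fixed two-level shape, generated labels
    label_rng = np.random.default_rng([seed, 7])
    used: set[str] = set()
    classes: dict[str, OntologyClass] = {}
    root_id = "SD:0000"
    classes[root_id] = OntologyClass(
        id=root_id, primary_label=_unique_label(label_rng, "d", used)
    )
    category_ids = []
    for c in range(n_categories):
        cid = f"SD:C{c:03d}"
        category_ids.append(cid)
        classes[cid] = OntologyClass(
            id=cid,
            primary_label=_unique_label(label_rng, "d", used),
            parent_ids=frozenset({root_id}),
        )
    disease_ids = []
    categories: dict[str, set[str]] = {}
    for i in range(n_diseases):
        did = f"SD:D{i:03d}"
        disease_ids.append(did)
        cat = category_ids[i % n_categories]
        categories[did] = {cat}
        synonyms: frozenset[str] = frozenset()
        if label_rng.random() < 0.25:
            synonyms = frozenset({_unique_label(label_rng, "d", used)})
        classes[did] = OntologyClass(
            id=did,
            primary_label=_unique_label(label_rng, "d", used),
            synonyms=synonyms,
            parent_ids=frozenset({cat}),
        )
    disease_ontology = Ontology(classes)

    phenotype_ontology = generate_ontology(
        seed, n_classes=n_phenotype_classes, max_parents=2, synonym_rate=0.25,
        id_prefix="SP", label_tag="p",
    )
    non_root = sorted(
        cid for cid in phenotype_ontology.classes if phenotype_ontology[cid].parent_ids
    )
    chosen = [non_root[j] for j in rng.choice(len(non_root), size=needed, replace=False)]
    truth_profiles: dict[str, frozenset[str]] = {}
    signature_weights: dict[str, dict[str, float]] = {}
    if shared_scheme:
        n_unique = signature_size - 2
        shared = chosen[: n_diseases]  # shared[i] links disease i and i+1
        unique = chosen[n_diseases:]
        for i, did in enumerate(disease_ids):
            own_unique = unique[i * n_unique : (i + 1) * n_unique]
            cardinals = [shared[(i - 1) % n_diseases], shared[i]]
            truth_profiles[did] = frozenset(cardinals) | frozenset(own_unique)
            signature_weights[did] = {c: cardinal_weight for c in cardinals}
    else:
        for i, did in enumerate(disease_ids):
            truth_profiles[did] = frozenset(
                chosen[i * signature_size : (i + 1) * signature_size]
            )

    corpus = generate_corpus(
        seed, truth_profiles, disease_ontology, phenotype_ontology,
        n_docs=n_docs, signal_rate=signal_rate, noise_rate=noise_rate,
        comention_rate=comention_rate,
        signature_weights=signature_weights or None,
    )
    model_profiles, eval_positives = generate_annotations(
        seed, truth_profiles, phenotype_ontology,
        n_models=n_models, positive_fraction=positive_fraction,
        corruption_rate=corruption_rate,
    )
    return SyntheticBundle(
        disease_ontology=disease_ontology,
        phenotype_ontology=phenotype_ontology,
        corpus=corpus,
        truth_profiles=truth_profiles,
        model_profiles=model_profiles,
        eval_positives=eval_positives,
        categories=categories,
        seed=seed,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the pipeline's input formats; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "disease_obo": outdir / "disease.obo",
        "phenotype_obo": outdir / "phenotype.obo",
        "corpus_tsv": outdir / "corpus.tsv",
        "model_profiles_tsv": outdir / "model_profiles.tsv",
        "truth_profiles_tsv": outdir / "truth_profiles.tsv",
        "positives_tsv": outdir / "positives.tsv",
        "categories_tsv": outdir / "categories.tsv",
    }
    write_obo(bundle.disease_ontology, paths["disease_obo"], name="synthetic-disease")
    write_obo(bundle.phenotype_ontology, paths["phenotype_obo"], name="synthetic-phenotype")
    write_corpus_tsv(bundle.corpus, paths["corpus_tsv"])
    write_profiles_tsv(bundle.model_profiles, paths["model_profiles_tsv"])
    with open(paths["truth_profiles_tsv"], "w", encoding="utf-8") as fh:
        fh.write("disease_id\tphenotype_id\n")
        for did in sorted(bundle.truth_profiles):
            for pid in sorted(bundle.truth_profiles[did]):
                fh.write(f"{did}\t{pid}\n")
    with open(paths["positives_tsv"], "w", encoding="utf-8") as fh:
        fh.write("entity_id\tdisease_id\n")
        for entity_id, disease_id in sorted(bundle.eval_positives.positives):
            fh.write(f"{entity_id}\t{disease_id}\n")
    with open(paths["categories_tsv"], "w", encoding="utf-8") as fh:
        fh.write("disease_id\tcategory_id\n")
        for did in sorted(bundle.categories):
            for cat in sorted(bundle.categories[did]):
                fh.write(f"{did}\t{cat}\n")
    return paths
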