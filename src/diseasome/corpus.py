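"""Corpus normalization, term matching and disease–phenotype co-occurrence counting.

Documents are title + abstract records.  Text is tokenized, lower-cased and
stop-word filtered; a class mentions a document when any of its terms (a
normalized label or synonym phrase) occurs contiguously in the title or the
abstract.  All counts are counts of distinct documents, never of mentions:
a document mentioning a disease three times contributes one to ``n_D``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .ontology import TermSet

__all__ = [
    "Document",
    "Corpus",
    "CooccurrenceCounts",
    "EmptyCorpusError",
    "STOP_WORDS",
    "normalize_text",
    "matches",
    "filter_corpus",
    "count_cooccurrence",
    "matching_documents",
    "cooccurrence_table",
    "read_corpus_tsv",
    "read_corpus_jsonl",
    "write_corpus_tsv",
    "write_counts_tsv",
]

# The classic Lucene/Snowball English stop list (33 words). Tokens on this
# list never take part in phrase matching.
STOP_WORDS: frozenset[str] = frozenset(
    """a an and are as at be but by for if in into is it no not of on or such
    that the their then there these they this to was will with""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class EmptyCorpusError(ValueError):
    """Raised when corpus filtering leaves no documents (scores undefined)."""


@dataclass(frozen=True)
class Document:
    doc_id: str
    title: str
    abstract: str


class Corpus:
    """A filtered document collection with per-class match sets precomputed lazily."""

    def __init__(self, documents: Sequence[Document]):
        self.documents: list[Document] = list(documents)
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate doc_id in corpus")
        # each document yields two token sequences (title, abstract); a phrase
        # may not span the title/abstract junction
        self._tokens: list[tuple[list[str], list[str]]] = [
            (normalize_text(d.title), normalize_text(d.abstract)) for d in self.documents
        ]

    @property
    def n_tot(self) -> int:
        return len(self.documents)

    def token_fields(self, index: int) -> tuple[list[str], list[str]]:
        return self._tokens[index]


@dataclass(frozen=True)
class CooccurrenceCounts:
    """The count quadruple (n_D, n_P, n_DP, n_tot) for one disease–phenotype pair."""

    disease_id: str
    phenotype_id: str
    n_D: int
    n_P: int
    n_DP: int
    n_tot: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_DP <= min(self.n_D, self.n_P) <= self.n_tot):
            raise ValueError(
                f"inconsistent counts for ({self.disease_id}, {self.phenotype_id}): "
                f"n_D={self.n_D} n_P={self.n_P} n_DP={self.n_DP} n_tot={self.n_tot}"
            )


def normalize_text(text: str) -> list[str]:
    """Tokenize, lower-case and stop-word filter a text.

    Tokens are maximal runs of ASCII alphanumerics; everything else
    (punctuation, hyphens, whitespace) is a separator.  Deterministic and
    idempotent: re-normalizing the joined output returns the same tokens.
    """
    return [t for t in _TOKEN_RE.findall(text.lower()) if t not in STOP_WORDS]


def _contains_phrase(tokens: Sequence[str], phrase: Sequence[str]) -> bool:
    k = len(phrase)
    if k == 0 or k > len(tokens):
        return False
    first = phrase[0]
    phrase = tuple(phrase)
    for i, tok in enumerate(tokens[: len(tokens) - k + 1]):
        if tok == first and tuple(tokens[i : i + k]) == phrase:
            return True
    return False


def matches(document: Document, term_set: TermSet) -> bool:
    """True iff any term occurs contiguously in the normalized title or abstract."""
    title = normalize_text(document.title)
    abstract = normalize_text(document.abstract)
    return any(
        _contains_phrase(title, term) or _contains_phrase(abstract, term)
        for term in term_set.terms
    )


def matching_documents(corpus: Corpus, term_set: TermSet) -> set[int]:
    """Indices of corpus documents matched by the term set (``Docs(q)``)."""
    hits: set[int] = set()
    for i in range(corpus.n_tot):
        title, abstract = corpus.token_fields(i)
        for term in term_set.terms:
            if _contains_phrase(title, term) or _contains_phrase(abstract, term):
                hits.add(i)
                break
    return hits


def filter_corpus(documents: Iterable[Document], all_term_sets: Iterable[TermSet]) -> Corpus:
    """Restrict the corpus to documents mentioning at least one ontology term."""
    term_sets = list(all_term_sets)
    kept = [
        doc for doc in documents if any(matches(doc, ts) for ts in term_sets)
    ]
    if not kept:
        raise EmptyCorpusError("no document matches any ontology term")
    return Corpus(kept)


def count_cooccurrence(
    corpus: Corpus, disease_terms: TermSet, phenotype_terms: TermSet
) -> CooccurrenceCounts:
    """Count documents matching the disease terms, the phenotype terms, and both.

    Matching either term set is an OR over its terms; co-occurrence is the
    AND of the two matches at document level.
    """
    if corpus.n_tot == 0:
        raise EmptyCorpusError("cannot count over an empty corpus")
    docs_d = matching_documents(corpus, disease_terms)
    docs_p = matching_documents(corpus, phenotype_terms)
    return CooccurrenceCounts(
        disease_id=disease_terms.class_id,
        phenotype_id=phenotype_terms.class_id,
        n_D=len(docs_d),
        n_P=len(docs_p),
        n_DP=len(docs_d & docs_p),
        n_tot=corpus.n_tot,
    )


def cooccurrence_table(
    corpus: Corpus,
    disease_term_sets: Sequence[TermSet],
    phenotype_term_sets: Sequence[TermSet],
) -> list[CooccurrenceCounts]:
    """All-pairs co-occurrence counts, computing each class's match set once.

    Pairs that never co-occur (``n_DP = 0``) are omitted: they carry no
    collocation signal and their scores are undefined.
    """
    if corpus.n_tot == 0:
        raise EmptyCorpusError("cannot count over an empty corpus")
    disease_docs = {ts.class_id: matching_documents(corpus, ts) for ts in disease_term_sets}
    phenotype_docs = {ts.class_id: matching_documents(corpus, ts) for ts in phenotype_term_sets}
    out: list[CooccurrenceCounts] = []
    for did, ddocs in disease_docs.items():
        if not ddocs:
            continue
        for pid, pdocs in phenotype_docs.items():
            n_dp = len(ddocs & pdocs)
            if n_dp:
                out.append(
                    CooccurrenceCounts(
                        disease_id=did,
                        phenotype_id=pid,
                        n_D=len(ddocs),
                        n_P=len(pdocs),
                        n_DP=n_dp,
                        n_tot=corpus.n_tot,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# I/O

def read_corpus_tsv(path: str | Path) -> list[Document]:
    """Read documents from a TSV with columns doc_id, title, abstract (no header)."""
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            doc_id, title, abstract = line.split("\t", 2)
            docs.append(Document(doc_id=doc_id, title=title, abstract=abstract))
    return docs


def read_corpus_jsonl(path: str | Path) -> list[Document]:
    """Read documents from JSONL with keys doc_id, title, abstract."""
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            docs.append(
                Document(doc_id=str(obj["doc_id"]), title=obj["title"], abstract=obj["abstract"])
            )
    return docs


def write_corpus_tsv(documents: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in documents:
            title = doc.title.replace("\t", " ").replace("\n", " ")
            abstract = doc.abstract.replace("\t", " ").replace("\n", " ")
            fh.write(f"{doc.doc_id}\t{title}\t{abstract}\n")


def write_counts_tsv(counts: Iterable[CooccurrenceCounts], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tphenotype_id\tn_D\tn_P\tn_DP\tn_tot\n")
        for c in counts:
            fh.write(f"{c.disease_id}\t{c.phenotype_id}\t{c.n_D}\t{c.n_P}\t{c.n_DP}\t{c.n_tot}\n")
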