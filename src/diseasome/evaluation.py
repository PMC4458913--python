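"""ROC machinery and the evaluation procedures for text-mined disease phenotypes.

The central statistic is the area under the ROC curve in its Mann–Whitney
form: the probability that a randomly chosen positive pair scores higher
than a randomly chosen negative pair, with ties counting one half.  Known
associations (gene–disease, genotype–disease, shared-drug disease pairs,
same-category diseases) are the positives; every other scored pair is
treated as a negative.  Because the positive lists are assumed exhaustive
and certainly are not, reported AUCs are lower bounds on true performance.

The standard-error estimate is sigma = sqrt(AUC (1 - AUC) / min(m, n)) with
m positives and n negatives, and AUC ± 2 sigma serves as an approximate 95%
confidence interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .ontology import Ontology, superclass_closure
from .scoring import DiseaseProfile
from .similarity import SimilarityMatrix

__all__ = [
    "EvaluationDataset",
    "ROCResult",
    "OverlapResult",
    "UndefinedAUCError",
    "roc_auc",
    "auc_from_labels",
    "per_query_retrieval_auc",
    "category_coherence",
    "phenotype_overlap",
    "shared_drug_pairs",
    "drug_sharing_auc",
    "merge_profiles",
    "read_positives_tsv",
    "read_indications_tsv",
    "read_categories_tsv",
    "write_roc_tsv",
]


class UndefinedAUCError(ValueError):
    """AUC needs at least one positive and one negative instance."""


@dataclass(frozen=True)
class EvaluationDataset:
    """Known positive (entity, disease) associations, e.g. from OMIM or MGI."""

    positives: frozenset[tuple[str, str]]
    name: str = ""


@dataclass(frozen=True)
class ROCResult:
    auc: float
    sigma: float
    m: int  # positives
    n: int  # negatives
    curve: tuple[tuple[float, float], ...]  # (fpr, tpr) points

    @property
    def ci95(self) -> tuple[float, float]:
        return self.auc - 2 * self.sigma, self.auc + 2 * self.sigma


@dataclass(frozen=True)
class OverlapResult:
    jaccard: float
    coverage: float
    closed: bool


def auc_from_labels(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """Mann–Whitney AUC with tie-halving, plus the ROC curve and sigma."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    m = int(y.sum())
    n = int((~y).sum())
    if m == 0 or n == 0:
        raise UndefinedAUCError(f"need positives and negatives, got m={m}, n={n}")
    ranks = rankdata(s)  # average ranks: ties contribute 1/2
    auc = (ranks[y].sum() - m * (m + 1) / 2) / (m * n)
    sigma = math.sqrt(auc * (1 - auc) / min(m, n))
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    curve = tuple(zip(fpr.tolist(), tpr.tolist()))
    return ROCResult(auc=float(auc), sigma=sigma, m=m, n=n, curve=curve)


def roc_auc(
    scores: Mapping[tuple[str, str], float], positives: EvaluationDataset
) -> ROCResult:
    """AUC over scored (entity, disease) pairs; unlisted pairs are negatives."""
    keys = sorted(scores)
    labels = [k in positives.positives for k in keys]
    return auc_from_labels([scores[k] for k in keys], labels)


def per_query_retrieval_auc(
    similarity: SimilarityMatrix,
    positives_per_query: Mapping[str, set[str]],
) -> ROCResult:
    """Pooled retrieval ROC: each query row ranks all targets except itself.

    Every (query, target) pair with target != query contributes one instance
    scored by the matrix entry; pairs listed for the query are positive.
    Queries without any positive target are skipped (they would contribute
    negatives only and dilute the pool).
    """
    col_index = {cid: j for j, cid in enumerate(similarity.col_ids)}
    scores: list[float] = []
    labels: list[bool] = []
    for query, targets in sorted(positives_per_query.items()):
        if query not in similarity.row_ids:
            raise KeyError(f"query {query!r} not in similarity matrix rows")
        if not (targets - {query}):
            continue
        i = similarity.row_ids.index(query)
        for cid, j in col_index.items():
            if cid == query:
                continue
            scores.append(float(similarity.values[i, j]))
            labels.append(cid in targets)
    if not scores:
        raise UndefinedAUCError("no query has a positive target")
    return auc_from_labels(scores, labels)


def category_coherence(
    similarity: SimilarityMatrix,
    categories: Mapping[str, set[str]],
) -> dict[str, ROCResult]:
    """Phenotypic coherence of each disease category.

    For each category, each member disease queries the matrix and the other
    members are its positives; all queries pool into one ROC per category.
    A disease belonging to several categories is a positive for each of
    them.  Categories with fewer than two member diseases in the matrix are
    skipped with a warning.
    """
    if not similarity.is_square:
        raise ValueError("category coherence needs a square disease-disease matrix")
    diseases = set(similarity.row_ids)
    members: dict[str, set[str]] = {}
    for disease, cats in categories.items():
        if disease not in diseases:
            continue
        for cat in cats:
            members.setdefault(cat, set()).add(disease)
    results: dict[str, ROCResult] = {}
    for cat in sorted(members):
        group = members[cat]
        if len(group) < 2:
            warnings.warn(f"category {cat!r} has fewer than 2 diseases; skipped")
            continue
        positives = {d: group - {d} for d in sorted(group)}
        try:
            results[cat] = per_query_retrieval_auc(similarity, positives)
        except UndefinedAUCError:
            warnings.warn(f"category {cat!r} covers every disease; skipped")
    return results


def phenotype_overlap(
    text_mined: set[str],
    reference: set[str],
    ontology: Ontology,
    closed: bool = False,
) -> OverlapResult:
    """Jaccard overlap and reference coverage of two phenotype sets.

    With ``closed=True`` both sets are first closed against superclasses, so
    agreement at a coarser level of description still counts.
    """
    if not reference:
        raise ValueError("reference set is empty; coverage undefined")
    a, b = set(text_mined), set(reference)
    if closed:
        a = superclass_closure(ontology, a)
        b = superclass_closure(ontology, b)
    inter = len(a & b)
    return OverlapResult(
        jaccard=inter / len(a | b),
        coverage=inter / len(b),
        closed=closed,
    )


def shared_drug_pairs(
    indications: Mapping[str, set[str]],
) -> set[frozenset[str]]:
    """Unordered disease pairs treated by at least one common drug."""
    pairs: set[frozenset[str]] = set()
    for diseases in indications.values():
        ordered = sorted(diseases)
        for i, d1 in enumerate(ordered):
            for d2 in ordered[i + 1:]:
                pairs.add(frozenset((d1, d2)))
    return pairs


def drug_sharing_auc(
    similarity: SimilarityMatrix,
    shared_pairs: set[frozenset[str]],
) -> ROCResult:
    """Probability that a drug-sharing disease pair outranks a non-sharing pair.

    Every unordered off-diagonal disease pair is scored by its similarity;
    pairs sharing a drug are the positives.
    """
    if not similarity.is_square:
        raise ValueError("drug-sharing evaluation needs a square matrix")
    if not shared_pairs:
        raise UndefinedAUCError("no shared-drug pairs supplied")
    ids = similarity.row_ids
    scores: list[float] = []
    labels: list[bool] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            scores.append(float(similarity.values[i, j]))
            labels.append(frozenset((ids[i], ids[j])) in shared_pairs)
    return auc_from_labels(scores, labels)


def merge_profiles(a: DiseaseProfile, b: DiseaseProfile) -> DiseaseProfile:
    """Union of two phenotype profiles for the same disease."""
    if a.disease_id != b.disease_id:
        raise ValueError(f"cannot merge profiles of {a.disease_id!r} and {b.disease_id!r}")
    return DiseaseProfile(
        disease_id=a.disease_id, phenotype_ids=a.phenotype_ids | b.phenotype_ids
    )


# ---------------------------------------------------------------------------
# I/O

def read_positives_tsv(path: str | Path, name: str = "") -> EvaluationDataset:
    """Read positive pairs from TSV rows (entity_id, disease_id)."""
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            entity_id, disease_id = line.rstrip("\n").split("\t")
            pairs.add((entity_id, disease_id))
    return EvaluationDataset(positives=frozenset(pairs), name=name or str(path))


def read_indications_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read drug indications from TSV rows (drug_id, disease_id)."""
    indications: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            drug_id, disease_id = line.rstrip("\n").split("\t")
            indications.setdefault(drug_id, set()).add(disease_id)
    return indications


def read_categories_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read disease categories from TSV rows (disease_id, category_id)."""
    categories: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            disease_id, cat = line.rstrip("\n").split("\t")
            categories.setdefault(disease_id, set()).add(cat)
    return categories


def write_roc_tsv(result: ROCResult, path: str | Path) -> None:
    """Write curve points plus a trailing summary line (auc, sigma, m, n)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in result.curve:
            fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")
        fh.write(f"#auc={result.auc:.10g}\tsigma={result.sigma:.10g}\tm={result.m}\tn={result.n}\n")
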