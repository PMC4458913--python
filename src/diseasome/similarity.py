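"""Corpus-based information content and simGIC semantic similarity.

An annotation profile is a set of ontology classes describing an entity
(the phenotypes associated with a disease, or observed in a mouse model or
mutant genotype).  Profiles are compared after closing each against the
superclass relation, so a specific annotation also counts as all of its
ancestors.

Information content is estimated from an annotation corpus — here, the
collection of profiles under analysis (mouse models and diseases together):
IC(x) = -ln p(x), where p(x) is the fraction of entities whose closed
profile contains x.  Classes annotated to every entity (in particular any
shared root) have IC 0 and therefore carry no similarity signal; classes
never annotated are absent from the map and contribute nothing to either
sum.

simGIC is the information-content-weighted Jaccard index of the two closed
profiles:

    simGIC(A, B) = sum_{c in Cl(A) ∩ Cl(B)} IC(c) / sum_{c in Cl(A) ∪ Cl(B)} IC(c)

bounded in [0, 1], 1 for identical closures with any informative class, and
0 when the closures share only uninformative ancestors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ontology import Ontology, superclass_closure

__all__ = [
    "AnnotationProfile",
    "ICMap",
    "SimilarityMatrix",
    "information_content",
    "simgic",
    "similarity_matrix",
    "read_profiles_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_matrix_long_tsv",
]

ENTITY_KINDS = ("disease", "genotype", "gene")


@dataclass(frozen=True)
class AnnotationProfile:
    """A set of phenotype classes annotated to one entity."""

    entity_id: str
    phenotype_ids: frozenset[str]
    entity_kind: str = "disease"

    def __post_init__(self) -> None:
        if not self.phenotype_ids:
            raise ValueError(f"profile for {self.entity_id!r} is empty")
        if self.entity_kind not in ENTITY_KINDS:
            raise ValueError(f"unknown entity kind {self.entity_kind!r}")


@dataclass(frozen=True)
class ICMap:
    """Information content per class, in nats; unannotated classes are absent."""

    values: Mapping[str, float]

    def __getitem__(self, class_id: str) -> float:
        return self.values.get(class_id, 0.0)


@dataclass(frozen=True)
class SimilarityMatrix:
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match id lists")

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def lookup(self, row_id: str, col_id: str) -> float:
        return float(
            self.values[self.row_ids.index(row_id), self.col_ids.index(col_id)]
        )


def information_content(
    profiles: Sequence[AnnotationProfile], ontology: Ontology
) -> ICMap:
    """IC(x) = -ln(fraction of entities whose closed profile contains x).

    The annotation corpus is exactly the profiles passed in; pass diseases
    and models together to reproduce a joint-corpus IC.
    """
    if not profiles:
        raise ValueError("information_content requires at least one profile")
    counts: dict[str, int] = {}
    for profile in profiles:
        for cid in superclass_closure(ontology, profile.phenotype_ids):
            counts[cid] = counts.get(cid, 0) + 1
    n = len(profiles)
    return ICMap(values={cid: -math.log(c / n) for cid, c in counts.items()})


def simgic(
    profile_a: AnnotationProfile,
    profile_b: AnnotationProfile,
    ic: ICMap,
    ontology: Ontology,
) -> float:
    """Information-content-weighted Jaccard similarity of two closed profiles."""
    closed_a = superclass_closure(ontology, profile_a.phenotype_ids)
    closed_b = superclass_closure(ontology, profile_b.phenotype_ids)
    num = sum(ic[c] for c in closed_a & closed_b)
    den = sum(ic[c] for c in closed_a | closed_b)
    if den == 0.0:
        return 0.0
    return num / den


def similarity_matrix(
    rows: Sequence[AnnotationProfile],
    cols: Sequence[AnnotationProfile],
    ic: ICMap,
    ontology: Ontology,
) -> SimilarityMatrix:
    """All-pairs simGIC between two profile collections.

    Closures and per-closure IC sums are computed once per profile, so the
    cost per matrix entry is one sparse intersection.
    """
    def closures(profiles: Sequence[AnnotationProfile]) -> list[dict[str, float]]:
        out = []
        for p in profiles:
            closed = superclass_closure(ontology, p.phenotype_ids)
            out.append({c: ic[c] for c in closed})
        return out

    row_closed = closures(rows)
    col_closed = closures(cols)
    row_sums = [sum(d.values()) for d in row_closed]
    col_sums = [sum(d.values()) for d in col_closed]
    values = np.zeros((len(rows), len(cols)))
    for i, a in enumerate(row_closed):
        for j, b in enumerate(col_closed):
            small, large = (a, b) if len(a) <= len(b) else (b, a)
            inter = sum(w for c, w in small.items() if c in large)
            den = row_sums[i] + col_sums[j] - inter
            values[i, j] = inter / den if den > 0 else 0.0
    return SimilarityMatrix(
        row_ids=tuple(p.entity_id for p in rows),
        col_ids=tuple(p.entity_id for p in cols),
        values=values,
    )


# ---------------------------------------------------------------------------
# I/O

def read_profiles_tsv(path: str | Path) -> list[AnnotationProfile]:
    """Read profiles from TSV rows (entity_id, entity_kind, phenotype_id)."""
    rows: dict[tuple[str, str], set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            entity_id, kind, pid = line.rstrip("\n").split("\t")
            rows.setdefault((entity_id, kind), set()).add(pid)
    return [
        AnnotationProfile(entity_id=eid, entity_kind=kind, phenotype_ids=frozenset(pids))
        for (eid, kind), pids in sorted(rows.items())
    ]


def write_profiles_tsv(profiles: Iterable[AnnotationProfile], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity_id\tentity_kind\tphenotype_id\n")
        for p in sorted(profiles, key=lambda p: p.entity_id):
            for pid in sorted(p.phenotype_ids):
                fh.write(f"{p.entity_id}\t{p.entity_kind}\t{pid}\n")


def write_matrix_tsv(matrix: SimilarityMatrix, path: str | Path) -> None:
    """Write the matrix in wide form (rows × columns, first column = row id)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(("", *matrix.col_ids)) + "\n")
        for i, rid in enumerate(matrix.row_ids):
            fh.write(rid + "\t" + "\t".join(f"{v:.10g}" for v in matrix.values[i]) + "\n")


def read_matrix_tsv(path: str | Path) -> SimilarityMatrix:
    with open(path, encoding="utf-8") as fh:
        col_ids = tuple(fh.readline().rstrip("\n").split("\t")[1:])
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            row_ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return SimilarityMatrix(row_ids=tuple(row_ids), col_ids=col_ids, values=np.array(rows))


def write_matrix_long_tsv(matrix: SimilarityMatrix, path: str | Path) -> None:
    """Write the matrix in long form (row_id, col_id, similarity)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("row_id\tcol_id\tsimilarity\n")
        for i, rid in enumerate(matrix.row_ids):
            for j, cid in enumerate(matrix.col_ids):
                fh.write(f"{rid}\t{cid}\t{matrix.values[i, j]:.10g}\n")
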