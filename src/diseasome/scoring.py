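"""Collocation scoring of disease–phenotype co-occurrences and rank cutoffs.

Four standard collocation measures are computed from the document-count
quadruple (n_D, n_P, n_DP, n_tot), with p(D) = n_D/n_tot, p(P) = n_P/n_tot
and p(D,P) = n_DP/n_tot:

* NPMI  = ln[p(D,P) / (p(D) p(P))] / (-ln p(D,P)),   bounded in [-1, 1]
* T     = (n_DP - n_D n_P / n_tot) / sqrt(n_DP)
* Z     = (n_DP - n_D n_P / n_tot) / sqrt(n_D n_P / n_tot)
* LMI   = n_DP * ln[p(D,P) / (p(D) p(P))]

Natural logarithms throughout (NPMI is base-invariant; the LMI scale is
thereby fixed to nats).  All four measures are zero at exact independence
(n_DP n_tot = n_D n_P) and share the sign of n_DP n_tot - n_D n_P.

NPMI is the primary score: per disease, associations are sorted by
decreasing NPMI, the best association sits on rank 0, and a disease profile
keeps the phenotypes on ranks 0..n-1.  Diseases without a strictly positive
NPMI at rank n-1 (i.e. with fewer than n positive associations) are
excluded from the analysis at cutoff n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .corpus import CooccurrenceCounts

if TYPE_CHECKING:  # pragma: no cover
    from .evaluation import EvaluationDataset
    from .ontology import Ontology
    from .similarity import AnnotationProfile

__all__ = [
    "ScoredAssociation",
    "DiseaseProfile",
    "UndefinedScoreError",
    "DegenerateCorpusError",
    "compute_scores",
    "score_association",
    "score_table",
    "rank_by_npmi",
    "rank_all",
    "apply_rank_cutoff",
    "select_optimal_cutoff",
    "read_association_tsv",
    "write_association_tsv",
    "write_profiles_tsv",
    "read_profiles_tsv",
]


class UndefinedScoreError(ValueError):
    """Scores are undefined for pairs that never co-occur (n_DP = 0)."""


class DegenerateCorpusError(ValueError):
    """NPMI is undefined when the pair co-occurs in every document."""


@dataclass(frozen=True)
class ScoredAssociation:
    disease_id: str
    phenotype_id: str
    npmi: float
    t_score: float
    z_score: float
    lmi: float
    rank: int = -1  # assigned by rank_by_npmi; -1 = unranked


@dataclass(frozen=True)
class DiseaseProfile:
    """The phenotype classes retained for one disease after the rank cutoff."""

    disease_id: str
    phenotype_ids: frozenset[str]


def compute_scores(counts: CooccurrenceCounts) -> tuple[float, float, float, float]:
    """Return (npmi, t_score, z_score, lmi) for one count quadruple."""
    if counts.n_DP == 0:
        raise UndefinedScoreError(
            f"({counts.disease_id}, {counts.phenotype_id}) never co-occurs"
        )
    if counts.n_DP == counts.n_tot:
        raise DegenerateCorpusError(
            f"({counts.disease_id}, {counts.phenotype_id}) co-occurs in every document"
        )
    n_tot = counts.n_tot
    p_dp = counts.n_DP / n_tot
    expected = counts.n_D * counts.n_P / n_tot
    pmi = math.log(counts.n_DP * n_tot / (counts.n_D * counts.n_P))
    # clamp against float roundoff at the perfect-co-occurrence endpoint
    npmi = max(-1.0, min(1.0, pmi / (-math.log(p_dp))))
    t_score = (counts.n_DP - expected) / math.sqrt(counts.n_DP)
    z_score = (counts.n_DP - expected) / math.sqrt(expected)
    lmi = counts.n_DP * pmi
    return npmi, t_score, z_score, lmi


def score_association(counts: CooccurrenceCounts) -> ScoredAssociation:
    npmi, t, z, lmi = compute_scores(counts)
    return ScoredAssociation(
        disease_id=counts.disease_id,
        phenotype_id=counts.phenotype_id,
        npmi=npmi,
        t_score=t,
        z_score=z,
        lmi=lmi,
    )


def score_table(counts: Iterable[CooccurrenceCounts]) -> list[ScoredAssociation]:
    """Score every count quadruple; the input must already omit n_DP = 0 pairs."""
    return [score_association(c) for c in counts]


def rank_by_npmi(scored: Sequence[ScoredAssociation]) -> list[ScoredAssociation]:
    """Sort one disease's associations by decreasing NPMI and assign ranks 0..k-1.

    Ties in NPMI are broken by phenotype id ascending, so profiles are
    reproducible regardless of input order.
    """
    if not scored:
        return []
    disease_ids = {a.disease_id for a in scored}
    if len(disease_ids) > 1:
        raise ValueError(f"rank_by_npmi expects one disease, got {sorted(disease_ids)}")
    ordered = sorted(scored, key=lambda a: (-a.npmi, a.phenotype_id))
    return [replace(a, rank=i) for i, a in enumerate(ordered)]


def rank_all(scored: Iterable[ScoredAssociation]) -> dict[str, list[ScoredAssociation]]:
    """Group associations by disease and rank each group by NPMI."""
    by_disease: dict[str, list[ScoredAssociation]] = {}
    for a in scored:
        by_disease.setdefault(a.disease_id, []).append(a)
    return {did: rank_by_npmi(group) for did, group in sorted(by_disease.items())}


def apply_rank_cutoff(
    ranked: Mapping[str, Sequence[ScoredAssociation]], n: int
) -> dict[str, DiseaseProfile]:
    """Keep the top-n phenotypes per disease; drop diseases lacking signal at rank n.

    A disease whose association at rank n-1 has NPMI <= 0 — equivalently,
    with fewer than n strictly positive-NPMI associations — is excluded
    entirely rather than given a shorter profile, so every retained disease
    carries exactly n phenotypes.
    """
    if n < 1:
        raise ValueError("cutoff n must be >= 1")
    profiles: dict[str, DiseaseProfile] = {}
    for disease_id, assocs in ranked.items():
        if len(assocs) < n or assocs[n - 1].npmi <= 0:
            continue
        profiles[disease_id] = DiseaseProfile(
            disease_id=disease_id,
            phenotype_ids=frozenset(a.phenotype_id for a in assocs[:n]),
        )
    return profiles


def select_optimal_cutoff(
    ranked: Mapping[str, Sequence[ScoredAssociation]],
    model_profiles: "Sequence[AnnotationProfile]",
    eval_positives: "EvaluationDataset",
    candidate_ns: Sequence[int],
    ontology: "Ontology",
) -> tuple[int, dict[int, float | None]]:
    """Choose the rank cutoff that maximizes gene/model-retrieval ROC AUC.

    For each candidate n the disease profiles at cutoff n are built, their
    simGIC similarity to every model profile is computed (information content
    taken over the union of disease and model profiles, the analysis corpus),
    and all (model, disease) pairs are pooled into one ROC against the known
    positive pairs.  Returns the best n and the full AUC-vs-n curve; cutoffs
    where no positive pair is retrievable get ``None`` and are skipped for
    the argmax.  Ties prefer the smaller cutoff.
    """
    from .evaluation import UndefinedAUCError, roc_auc
    from .similarity import AnnotationProfile, information_content, similarity_matrix

    if not candidate_ns:
        raise ValueError("candidate_ns must be non-empty")
    aucs: dict[int, float | None] = {}
    for n in candidate_ns:
        profiles = apply_rank_cutoff(ranked, n)
        if not profiles:
            aucs[n] = None
            continue
        disease_profiles = [
            AnnotationProfile(entity_id=d.disease_id, phenotype_ids=d.phenotype_ids,
                              entity_kind="disease")
            for d in profiles.values()
        ]
        ic = information_content(list(disease_profiles) + list(model_profiles), ontology)
        sim = similarity_matrix(list(model_profiles), disease_profiles, ic, ontology)
        scores = {
            (m, d): sim.values[i, j]
            for i, m in enumerate(sim.row_ids)
            for j, d in enumerate(sim.col_ids)
        }
        try:
            aucs[n] = roc_auc(scores, eval_positives).auc
        except UndefinedAUCError:
            aucs[n] = None
    defined = [(n, a) for n, a in aucs.items() if a is not None]
    if not defined:
        raise ValueError("no candidate cutoff yields a defined AUC")
    best_n = max(defined, key=lambda item: (item[1], -item[0]))[0]
    return best_n, aucs


# ---------------------------------------------------------------------------
# I/O

def write_association_tsv(
    ranked: Mapping[str, Sequence[ScoredAssociation]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tphenotype_id\tnpmi\tt_score\tz_score\tlmi\trank\n")
        for disease_id in sorted(ranked):
            for a in ranked[disease_id]:
                fh.write(
                    f"{a.disease_id}\t{a.phenotype_id}\t{a.npmi:.10g}\t"
                    f"{a.t_score:.10g}\t{a.z_score:.10g}\t{a.lmi:.10g}\t{a.rank}\n"
                )


def read_association_tsv(path: str | Path) -> dict[str, list[ScoredAssociation]]:
    by_disease: dict[str, list[ScoredAssociation]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("disease_id"):
            raise ValueError("association TSV must start with its header row")
        for line in fh:
            if not line.strip():
                continue
            did, pid, npmi, t, z, lmi, rank = line.rstrip("\n").split("\t")
            by_disease.setdefault(did, []).append(
                ScoredAssociation(
                    disease_id=did, phenotype_id=pid, npmi=float(npmi),
                    t_score=float(t), z_score=float(z), lmi=float(lmi), rank=int(rank),
                )
            )
    for group in by_disease.values():
        group.sort(key=lambda a: a.rank)
    return by_disease


def write_profiles_tsv(profiles: Mapping[str, DiseaseProfile], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tphenotype_id\n")
        for disease_id in sorted(profiles):
            for pid in sorted(profiles[disease_id].phenotype_ids):
                fh.write(f"{disease_id}\t{pid}\n")


def read_profiles_tsv(path: str | Path) -> dict[str, DiseaseProfile]:
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            did, pid = line.rstrip("\n").split("\t")
            sets.setdefault(did, set()).add(pid)
    return {
        did: DiseaseProfile(disease_id=did, phenotype_ids=frozenset(pids))
        for did, pids in sets.items()
    }
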