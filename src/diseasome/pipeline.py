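"""End-to-end orchestration: mine → score → cut → sim → eval → net → cluster.

Every stage is a pure function of the configuration and its input files and
writes plain-text artifacts into the output directory; a manifest records
the configuration and a checksum per artifact, so a rerun with the same
configuration reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import corpus as corpus_mod
from . import evaluation as eval_mod
from . import flame as flame_mod
from . import network as net_mod
from . import scoring as scoring_mod
from . import similarity as sim_mod
from .ontology import Ontology, load_obo, merge_ontologies, term_set

logger = logging.getLogger("diseasome")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    disease_obo: str
    phenotype_obos: list[str]
    corpus_path: str
    corpus_format: str = "tsv"  # tsv | jsonl
    model_profiles: str | None = None
    eval_positives: str | None = None
    reference_profiles: str | None = None  # curated disease profiles (overlap, self-retrieval)
    indications: str | None = None
    categories: str | None = None
    cutoff: int | str = "auto"
    cutoff_candidates: list[int] = field(default_factory=lambda: list(range(1, 51)))
    top_fraction: float = 0.005
    flame_k: int = 10
    flame_max_iter: int = 500
    flame_tol: float = 1e-6
    seed: int = 0
    outdir: str = "diseasome_out"

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must lie in (0, 1)")
        if isinstance(self.cutoff, str) and self.cutoff != "auto":
            raise ValueError("cutoff must be an integer or 'auto'")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw: dict[str, Any] = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log_stage(stage: str, msg: str) -> None:
    logger.info("[%s] %s %s", time.strftime("%H:%M:%S"), stage, msg)


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.artifacts: dict[str, Path] = {}

        self.disease_ontology = load_obo(config.disease_obo)
        phenos = [load_obo(p) for p in config.phenotype_obos]
        self.phenotype_ontology = phenos[0] if len(phenos) == 1 else merge_ontologies(*phenos)
        self.merged_ontology = merge_ontologies(self.disease_ontology, self.phenotype_ontology)

        self.corpus: corpus_mod.Corpus | None = None
        self.counts: list[corpus_mod.CooccurrenceCounts] | None = None
        self.ranked: dict[str, list[scoring_mod.ScoredAssociation]] | None = None
        self.cutoff_used: int | None = None
        self.profiles: dict[str, scoring_mod.DiseaseProfile] | None = None
        self.disease_disease: sim_mod.SimilarityMatrix | None = None
        self.disease_model: sim_mod.SimilarityMatrix | None = None

    # -- term sets ---------------------------------------------------------
    def _term_sets(self, ontology: Ontology):
        sets = []
        for cid in sorted(ontology.classes):
            if cid in ontology.roots:
                continue  # a root's lexicon covers the whole ontology
            ts = term_set(ontology, cid, corpus_mod.normalize_text)
            if ts.terms:
                sets.append(ts)
        return sets

    # -- stages ------------------------------------------------------------
    def mine(self) -> None:
        cfg = self.config
        reader = (
            corpus_mod.read_corpus_tsv if cfg.corpus_format == "tsv"
            else corpus_mod.read_corpus_jsonl
        )
        documents = reader(cfg.corpus_path)
        _log_stage("mine", f"read {len(documents)} documents")
        disease_sets = self._term_sets(self.disease_ontology)
        phenotype_sets = self._term_sets(self.phenotype_ontology)
        self.corpus = corpus_mod.filter_corpus(documents, disease_sets + phenotype_sets)
        _log_stage("mine", f"retained {self.corpus.n_tot} documents after term filtering")
        self.counts = corpus_mod.cooccurrence_table(
            self.corpus, disease_sets, phenotype_sets
        )
        _log_stage("mine", f"counted {len(self.counts)} co-occurring pairs")
        path = self.outdir / "counts.tsv"
        corpus_mod.write_counts_tsv(self.counts, path)
        self.artifacts["counts"] = path
        stats = self.outdir / "corpus_stats.tsv"
        with open(stats, "w", encoding="utf-8") as fh:
            fh.write(f"documents_in\t{len(documents)}\n")
            fh.write(f"documents_retained\t{self.corpus.n_tot}\n")
            fh.write(f"cooccurring_pairs\t{len(self.counts)}\n")
        self.artifacts["corpus_stats"] = stats

    def score(self) -> None:
        assert self.counts is not None
        scored = scoring_mod.score_table(self.counts)
        self.ranked = scoring_mod.rank_all(scored)
        _log_stage("score", f"ranked associations for {len(self.ranked)} diseases")
        path = self.outdir / "associations.tsv"
        scoring_mod.write_association_tsv(self.ranked, path)
        self.artifacts["associations"] = path

    def cut(self) -> None:
        cfg = self.config
        assert self.ranked is not None
        aucs: dict[int, float | None] = {}
        if cfg.cutoff == "auto":
            if not (cfg.model_profiles and cfg.eval_positives):
                raise PipelineError(
                    "cut: cutoff 'auto' needs model_profiles and eval_positives"
                )
            models = sim_mod.read_profiles_tsv(cfg.model_profiles)
            positives = eval_mod.read_positives_tsv(cfg.eval_positives)
            best_n, aucs = scoring_mod.select_optimal_cutoff(
                self.ranked, models, positives, cfg.cutoff_candidates,
                self.merged_ontology,
            )
            self.cutoff_used = best_n
        else:
            self.cutoff_used = int(cfg.cutoff)
        _log_stage("cut", f"using rank cutoff n={self.cutoff_used}")
        report = self.outdir / "cutoff_report.tsv"
        with open(report, "w", encoding="utf-8") as fh:
            fh.write("n\tauc\n")
            for n in sorted(aucs):
                a = aucs[n]
                fh.write(f"{n}\t{'' if a is None else f'{a:.10g}'}\n")
            fh.write(f"#chosen\t{self.cutoff_used}\n")
        self.artifacts["cutoff_report"] = report
        self.profiles = scoring_mod.apply_rank_cutoff(self.ranked, self.cutoff_used)
        _log_stage("cut", f"{len(self.profiles)} diseases retain a profile")
        path = self.outdir / "disease_profiles.tsv"
        scoring_mod.write_profiles_tsv(self.profiles, path)
        self.artifacts["disease_profiles"] = path

    def _disease_annotation_profiles(self) -> list[sim_mod.AnnotationProfile]:
        assert self.profiles is not None
        return [
            sim_mod.AnnotationProfile(
                entity_id=p.disease_id, phenotype_ids=p.phenotype_ids,
                entity_kind="disease",
            )
            for p in self.profiles.values()
        ]

    def sim(self) -> None:
        cfg = self.config
        diseases = self._disease_annotation_profiles()
        if not diseases:
            raise PipelineError("sim: no disease profile survived the cutoff")
        models = (
            sim_mod.read_profiles_tsv(cfg.model_profiles) if cfg.model_profiles else []
        )
        ic = sim_mod.information_content(diseases + list(models), self.merged_ontology)
        diseases = sorted(diseases, key=lambda p: p.entity_id)
        self.disease_disease = sim_mod.similarity_matrix(
            diseases, diseases, ic, self.merged_ontology
        )
        path = self.outdir / "disease_disease_similarity.tsv"
        sim_mod.write_matrix_tsv(self.disease_disease, path)
        self.artifacts["disease_disease_similarity"] = path
        if models:
            self.disease_model = sim_mod.similarity_matrix(
                sorted(models, key=lambda p: p.entity_id), diseases, ic,
                self.merged_ontology,
            )
            path = self.outdir / "model_disease_similarity.tsv"
            sim_mod.write_matrix_tsv(self.disease_model, path)
            self.artifacts["model_disease_similarity"] = path
        _log_stage("sim", f"similarity matrices over {len(diseases)} diseases")

    def evaluate(self) -> None:
        cfg = self.config
        summary: dict[str, Any] = {}
        if self.disease_model is not None and cfg.eval_positives:
            positives = eval_mod.read_positives_tsv(cfg.eval_positives)
            scores = {
                (m, d): float(self.disease_model.values[i, j])
                for i, m in enumerate(self.disease_model.row_ids)
                for j, d in enumerate(self.disease_model.col_ids)
            }
            roc = eval_mod.roc_auc(scores, positives)
            eval_mod.write_roc_tsv(roc, self.outdir / "roc_gene_retrieval.tsv")
            self.artifacts["roc_gene_retrieval"] = self.outdir / "roc_gene_retrieval.tsv"
            summary["gene_retrieval_auc"] = roc.auc
            summary["gene_retrieval_sigma"] = roc.sigma
        if cfg.reference_profiles and self.profiles:
            reference = scoring_mod.read_profiles_tsv(cfg.reference_profiles)
            common = sorted(self.profiles.keys() & reference.keys())
            if len(common) >= 2:
                mined = [
                    sim_mod.AnnotationProfile(d, self.profiles[d].phenotype_ids, "disease")
                    for d in common
                ]
                refs = [
                    sim_mod.AnnotationProfile(d, reference[d].phenotype_ids, "disease")
                    for d in common
                ]
                ic = sim_mod.information_content(mined + refs, self.merged_ontology)
                cross = sim_mod.similarity_matrix(mined, refs, ic, self.merged_ontology)
                scores = {
                    (a, b): float(cross.values[i, j])
                    for i, a in enumerate(cross.row_ids)
                    for j, b in enumerate(cross.col_ids)
                }
                self_pos = eval_mod.EvaluationDataset(
                    positives=frozenset((d, d) for d in common), name="self-retrieval"
                )
                roc = eval_mod.roc_auc(scores, self_pos)
                eval_mod.write_roc_tsv(roc, self.outdir / "roc_self_retrieval.tsv")
                self.artifacts["roc_self_retrieval"] = self.outdir / "roc_self_retrieval.tsv"
                summary["self_retrieval_auc"] = roc.auc
                overlaps = [
                    (
                        eval_mod.phenotype_overlap(
                            set(self.profiles[d].phenotype_ids),
                            set(reference[d].phenotype_ids),
                            self.merged_ontology, closed=False,
                        ),
                        eval_mod.phenotype_overlap(
                            set(self.profiles[d].phenotype_ids),
                            set(reference[d].phenotype_ids),
                            self.merged_ontology, closed=True,
                        ),
                    )
                    for d in common
                ]
                summary["mean_jaccard"] = sum(o.jaccard for o, _ in overlaps) / len(overlaps)
                summary["mean_jaccard_closed"] = sum(o.jaccard for _, o in overlaps) / len(overlaps)
                summary["mean_coverage"] = sum(o.coverage for o, _ in overlaps) / len(overlaps)
                summary["mean_coverage_closed"] = sum(o.coverage for _, o in overlaps) / len(overlaps)
        if cfg.indications and self.disease_disease is not None:
            indications = eval_mod.read_indications_tsv(cfg.indications)
            pairs = eval_mod.shared_drug_pairs(indications)
            known = set(self.disease_disease.row_ids)
            pairs = {p for p in pairs if p <= known}
            if pairs:
                roc = eval_mod.drug_sharing_auc(self.disease_disease, pairs)
                eval_mod.write_roc_tsv(roc, self.outdir / "roc_drug_sharing.tsv")
                self.artifacts["roc_drug_sharing"] = self.outdir / "roc_drug_sharing.tsv"
                summary["drug_sharing_auc"] = roc.auc
        if cfg.categories and self.disease_disease is not None:
            categories = eval_mod.read_categories_tsv(cfg.categories)
            coherence = eval_mod.category_coherence(self.disease_disease, categories)
            path = self.outdir / "category_coherence.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("category\tauc\tsigma\tm\tn\n")
                for cat, roc in sorted(coherence.items()):
                    fh.write(f"{cat}\t{roc.auc:.10g}\t{roc.sigma:.10g}\t{roc.m}\t{roc.n}\n")
            self.artifacts["category_coherence"] = path
        path = self.outdir / "evaluation_summary.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            for key in sorted(summary):
                fh.write(f"{key}\t{summary[key]:.10g}\n")
        self.artifacts["evaluation_summary"] = path
        _log_stage("eval", f"wrote {len(summary)} summary statistics")

    def net(self) -> None:
        cfg = self.config
        assert self.disease_disease is not None
        categories = (
            eval_mod.read_categories_tsv(cfg.categories) if cfg.categories else None
        )
        graph = net_mod.build_network(
            self.disease_disease, top_fraction=cfg.top_fraction, categories=categories
        )
        stats = net_mod.network_stats(graph)
        _log_stage(
            "net",
            f"{stats.node_count} nodes, {stats.edge_count} edges, "
            f"{stats.component_count} components",
        )
        net_mod.write_graphml(graph, self.outdir / "network.graphml")
        net_mod.write_edge_list_tsv(graph, self.outdir / "network_edges.tsv")
        net_mod.write_stats_tsv(stats, self.outdir / "network_stats.tsv")
        self.artifacts["network_graphml"] = self.outdir / "network.graphml"
        self.artifacts["network_edges"] = self.outdir / "network_edges.tsv"
        self.artifacts["network_stats"] = self.outdir / "network_stats.tsv"

    def cluster(self) -> None:
        cfg = self.config
        assert self.disease_disease is not None
        n = len(self.disease_disease.row_ids)
        k = min(cfg.flame_k, n - 1)
        result = flame_mod.flame_cluster(
            self.disease_disease, k=k, max_iter=cfg.flame_max_iter, tol=cfg.flame_tol
        )
        flame_mod.write_clustering_tsv(result, self.outdir / "clusters.tsv")
        self.artifacts["clusters"] = self.outdir / "clusters.tsv"
        report: dict[str, Any] = {"clusters": result.n_clusters}
        if cfg.categories:
            categories = eval_mod.read_categories_tsv(cfg.categories)
            clusters = flame_mod.hard_clusters(result)
            clusters = {
                label: {m for m in members if m in categories}
                for label, members in clusters.items()
            }
            clusters = {label: m for label, m in clusters.items() if m}
            if clusters:
                _, average_purity = flame_mod.cluster_purity(clusters, categories)
                report["average_purity"] = average_purity
                partition = flame_mod.categories_to_partition(categories)
                common = sorted(partition.keys() & result.cluster_of.keys())
                if len(common) >= 2:
                    comparison = flame_mod.rand_index(
                        {d: result.cluster_of[d] for d in common},
                        {d: partition[d] for d in common},
                    )
                    report["rand_index"] = comparison.rand
        path = self.outdir / "clustering_report.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in report.items():
                fh.write(f"{key}\t{value}\n")
        self.artifacts["clustering_report"] = path
        _log_stage("cluster", f"{result.n_clusters} clusters")

    def write_manifest(self) -> None:
        manifest = {
            "config": {k: getattr(self.config, k) for k in self.config.__dataclass_fields__},
            "seed": self.config.seed,
            "cutoff_used": self.cutoff_used,
            "artifacts": {
                name: {"path": str(path), "sha256": _sha256(path)}
                for name, path in sorted(self.artifacts.items())
            },
        }
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


_STAGES = ("mine", "score", "cut", "sim", "eval", "net", "cluster")


def run_pipeline(config: PipelineConfig, stages: Sequence[str] = _STAGES) -> _Run:
    """Run the requested stages in canonical order; abort naming the failed stage."""
    run = _Run(config)
    for stage in _STAGES:
        if stage not in stages:
            continue
        method = {"eval": run.evaluate}.get(stage) or getattr(run, stage)
        try:
            method()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    run.write_manifest()
    return run
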