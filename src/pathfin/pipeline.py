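"""End-to-end workflow: evidence -> scored interactions -> network ->
similarity matrices -> clustering -> pathway prediction -> regulation
reports. Deterministic given a config; every output is a text file."""

from __future__ import annotations

import logging
import time
from collections import defaultdict
from pathlib import Path

from . import io
from .cluster import cut_clusters, hierarchical_cluster, rank_references, similarity_to_distance
from .config import RunConfig
from .hin import (
    DrugTargetInteraction,
    build_network,
    filter_interactions,
    merge_composition_targets,
    score_interactions,
)
from .moa import classify_de, regulation_ratio, shared_pathway_subgraph
from .similarity import pathsim_matrix, target_similarity_matrix

log = logging.getLogger("pathfin")

__all__ = ["score_evidence_file", "run_pipeline"]


def score_evidence_file(
    evidence_path: str | Path,
    compositions_path: str | Path | None = None,
    threshold: float = 0.4,
) -> list[DrugTargetInteraction]:
    """Read evidence, combine per-source scores, merge compositions, filter.

    The threshold is applied AFTER the max-merge across compositions, so a
    target whose best composition clears the bar is kept even when other
    compositions scored below it.
    """
    evidence = io.read_evidence_tsv(evidence_path)
    interactions = score_interactions(evidence)
    if compositions_path:
        comp_map = io.read_composition_map(compositions_path)
        by_drug: dict[str, list[DrugTargetInteraction]] = defaultdict(list)
        for it in interactions:
            merged_id = comp_map.get(it.drug_id, it.drug_id)
            by_drug[merged_id].append(it)
        merged: list[DrugTargetInteraction] = []
        for drug in sorted(by_drug):
            per_comp: dict[str, list[DrugTargetInteraction]] = defaultdict(list)
            for it in by_drug[drug]:
                per_comp[it.drug_id].append(it)
            merged.extend(
                merge_composition_targets(list(per_comp.values()), drug_id=drug)
            )
        interactions = merged
    return filter_interactions(interactions, threshold)


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full workflow and write the report bundle under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def emit(key: str, name: str) -> Path:
        outputs[key] = outdir / name
        return outputs[key]

    try:
        t0 = _stage("score")
        interactions = score_evidence_file(
            config.evidence, config.compositions or None, config.cs_threshold
        )
        io.write_interactions_tsv(interactions, emit("interactions", "interactions.tsv"))
        log.info("score: %d interactions kept (%.2fs)", len(interactions),
                 time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"stage 'score' failed: {exc}") from exc

    try:
        _stage("build")
        gene_sets = []
        for gmt_path in config.gmt:
            gene_sets.extend(io.read_gmt(gmt_path, collection=Path(gmt_path).stem))
        network = build_network(interactions, gene_sets, config.cs_threshold)
        io.write_network(network, outdir / "network")
        outputs["network"] = outdir / "network"
    except Exception as exc:
        raise RuntimeError(f"stage 'build' failed: {exc}") from exc

    try:
        _stage("similarity")
        target_sim = target_similarity_matrix(network)
        path_sim = pathsim_matrix(network)
        io.write_similarity(target_sim, emit("target_similarity", "similarity_target.tsv"))
        io.write_similarity(path_sim, emit("pathsim", "similarity_pathsim.tsv"))
    except Exception as exc:
        raise RuntimeError(f"stage 'similarity' failed: {exc}") from exc

    try:
        _stage("cluster")
        for label, matrix in (("target", target_sim), ("pathsim", path_sim)):
            dendro = hierarchical_cluster(
                similarity_to_distance(matrix), matrix.drug_ids, config.linkage
            )
            (outdir / f"dendrogram_{label}.nwk").write_text(
                dendro.to_newick() + "\n", encoding="utf-8"
            )
            outputs[f"dendrogram_{label}"] = outdir / f"dendrogram_{label}.nwk"
            io.write_clusters(
                cut_clusters(dendro, config.n_clusters),
                emit(f"clusters_{label}", f"clusters_{label}.tsv"),
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'cluster' failed: {exc}") from exc

    if config.query:
        try:
            _stage("predict")
            if config.query not in path_sim.drug_ids:
                raise ValueError(f"query drug {config.query!r} not in network")
            reference = config.reference
            if not reference:
                reference = rank_references(path_sim, config.query)[0][0]
            ranking = shared_pathway_subgraph(network, config.query, reference)
            ranked = sorted(
                ranking.shares, key=lambda s: (-s.contribution, s.pathway_id)
            )
            with open(emit("predicted_pathways", "predicted_pathways.tsv"), "w",
                      encoding="utf-8") as fh:
                fh.write("pathway_id\tcontribution\tcommon\tquery_only\treference_only\n")
                for s in ranked:
                    fh.write(
                        f"{s.pathway_id}\t{s.contribution}\t"
                        + ",".join(sorted(s.common)) + "\t"
                        + ",".join(sorted(s.query_only)) + "\t"
                        + ",".join(sorted(s.reference_only)) + "\n"
                    )
            io.write_subgraph(
                ranking,
                emit("subgraph_edges", "subgraph_edges.tsv"),
                emit("subgraph_nodes", "subgraph_nodes.tsv"),
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'predict' failed: {exc}") from exc

    if config.de_table:
        try:
            _stage("regulate")
            records = io.read_de_table(config.de_table)
            by_contrast: dict[str, list] = defaultdict(list)
            for rec in records:
                by_contrast[rec.contrast].append(rec)
            reports = []
            for contrast in sorted(by_contrast):
                calls = classify_de(
                    by_contrast[contrast], config.fdr_cutoff, config.fc_cutoff
                )
                for gs in network.pathways:
                    reports.append(
                        regulation_ratio(calls, gs, contrast, config.ratio_policy)
                    )
            io.write_regulation_reports(reports, emit("regulation", "regulation.tsv"))
        except Exception as exc:
            raise RuntimeError(f"stage 'regulate' failed: {exc}") from exc

    config.to_yaml(emit("config", "config.yaml"))
    return outputs
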