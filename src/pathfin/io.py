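"""Readers and writers for the toolkit's text formats.

Formats: evidence TSV, composition-map TSV, GMT gene sets, network
directories (edge lists + JSON header + GMT), similarity matrices (TSV +
JSON sidecar), DE tables, regulation reports, subgraph exports. Floats are
printed with 6 significant digits so outputs are byte-stable.
"""

from __future__ import annotations

import json
import math
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .hin import (
    DrugTargetInteraction,
    GeneSet,
    HeterogeneousNetwork,
    SourceEvidence,
    map_bioassay_outcome,
)
from .moa import ExpressionRecord, MetapathSubgraph, RegulationReport
from .similarity import SimilarityMatrix

__all__ = [
    "read_evidence_tsv",
    "write_evidence_tsv",
    "read_composition_map",
    "read_gmt",
    "write_gmt",
    "read_interactions_tsv",
    "write_interactions_tsv",
    "read_network",
    "write_network",
    "read_similarity",
    "write_similarity",
    "read_de_table",
    "write_de_table",
    "write_regulation_reports",
    "write_clusters",
    "write_subgraph",
]


def fmt(x: float) -> str:
    """Canonical 6-significant-digit float rendering."""
    return format(float(x), ".6g")


class TableFormatError(ValueError):
    """A malformed row or header, reported with its line number."""


def _tsv_rows(path: str | Path):
    """Yield (line_number, fields) for non-comment, non-blank TSV lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


EVIDENCE_COLUMNS = ["drug_id", "target_id", "source", "probability"]


def read_evidence_tsv(path: str | Path) -> list[SourceEvidence]:
    """Read per-source drug-target evidence.

    The probability column accepts a number in [0, 1] or, for the pubchem
    channel, a bioassay outcome label. Target symbols are uppercased at
    ingestion. '#' comment lines are skipped; a header row is required.
    """
    rows = _tsv_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise TableFormatError(f"{path}: empty evidence file (header required)") from None
    if [h.strip().lower() for h in header] != EVIDENCE_COLUMNS:
        raise TableFormatError(
            f"{path}:1: expected header {EVIDENCE_COLUMNS}, got {header}"
        )
    records = []
    for lineno, fields in rows:
        if len(fields) != 4:
            raise TableFormatError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        drug, target, source, raw = (f.strip() for f in fields)
        try:
            try:
                prob = float(raw)
            except ValueError:
                prob = map_bioassay_outcome(raw)
            records.append(SourceEvidence(drug, target.upper(), source.lower(), prob))
        except ValueError as exc:
            raise TableFormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_evidence_tsv(records: Iterable[SourceEvidence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EVIDENCE_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.drug_id}\t{r.target_id}\t{r.source}\t{fmt(r.probability)}\n")


def read_composition_map(path: str | Path) -> dict[str, str]:
    """composition_id -> merged drug_id map (2-column TSV with header)."""
    rows = _tsv_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise TableFormatError(f"{path}: empty composition map") from None
    if [h.strip().lower() for h in header] != ["composition_id", "drug_id"]:
        raise TableFormatError(f"{path}:1: expected header composition_id, drug_id")
    mapping: dict[str, str] = {}
    for lineno, fields in rows:
        if len(fields) != 2:
            raise TableFormatError(f"{path}:{lineno}: expected 2 columns")
        comp, drug = fields[0].strip(), fields[1].strip()
        if comp in mapping:
            raise TableFormatError(f"{path}:{lineno}: duplicate composition {comp!r}")
        mapping[comp] = drug
    return mapping


def read_gmt(path: str | Path, collection: str = "") -> list[GeneSet]:
    """Standard GMT: set id <TAB> description <TAB> gene... Genes are
    uppercased and deduplicated."""
    sets = []
    for lineno, fields in _tsv_rows(path):
        if len(fields) < 3:
            raise TableFormatError(
                f"{path}:{lineno}: GMT rows need id, description and >=1 gene"
            )
        genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
        if not genes:
            raise TableFormatError(f"{path}:{lineno}: gene set {fields[0]!r} is empty")
        sets.append(GeneSet(fields[0].strip(), fields[1].strip(), genes, collection))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.pathway_id, gs.name, *sorted(gs.genes)]) + "\n")


INTERACTION_COLUMNS = ["drug_id", "target_id", "combined_score", "sources"]


def write_interactions_tsv(
    interactions: Iterable[DrugTargetInteraction], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(INTERACTION_COLUMNS) + "\n")
        for it in sorted(interactions, key=lambda i: (i.drug_id, i.target_id)):
            fh.write(
                f"{it.drug_id}\t{it.target_id}\t{fmt(it.combined_score)}\t"
                + ",".join(sorted(it.contributing_sources))
                + "\n"
            )


def read_interactions_tsv(path: str | Path) -> list[DrugTargetInteraction]:
    rows = _tsv_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise TableFormatError(f"{path}: empty interaction file") from None
    if [h.strip().lower() for h in header] != INTERACTION_COLUMNS:
        raise TableFormatError(f"{path}:1: expected header {INTERACTION_COLUMNS}")
    out = []
    for lineno, fields in rows:
        if len(fields) != 4:
            raise TableFormatError(f"{path}:{lineno}: expected 4 columns")
        try:
            out.append(
                DrugTargetInteraction(
                    fields[0].strip(),
                    fields[1].strip(),
                    float(fields[2]),
                    frozenset(s for s in fields[3].split(",") if s),
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_network(network: HeterogeneousNetwork, directory: str | Path) -> None:
    """Serialize a network as a directory: dt/tp edge lists, a GMT and a
    JSON header (threshold, drugs, collections)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "dt_edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("drug_id\ttarget_id\tcombined_score\n")
        for d, t in sorted(network.dt_edges):
            score = network.dt_scores.get((d, t), math.nan)
            fh.write(f"{d}\t{t}\t{fmt(score) if not math.isnan(score) else 'NA'}\n")
    with open(directory / "tp_edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("target_id\tpathway_id\n")
        for g, p in sorted(network.tp_edges):
            fh.write(f"{g}\t{p}\n")
    write_gmt(network.pathways, directory / "pathways.gmt")
    header = {
        "cs_threshold": network.cs_threshold,
        "drugs": sorted(network.drugs),
        "targets": sorted(network.targets),
        "pathway_names": {p.pathway_id: p.name for p in network.pathways},
        "collections": {p.pathway_id: p.collection for p in network.pathways},
        "content_hash": network.content_hash(),
    }
    (directory / "network.json").write_text(
        json.dumps(header, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_network(directory: str | Path) -> HeterogeneousNetwork:
    directory = Path(directory)
    header = json.loads((directory / "network.json").read_text(encoding="utf-8"))
    collections = header.get("collections", {})
    gene_sets = []
    for gs in read_gmt(directory / "pathways.gmt"):
        gene_sets.append(
            GeneSet(gs.pathway_id, gs.name, gs.genes, collections.get(gs.pathway_id, ""))
        )
    dt_edges, dt_scores = set(), {}
    for lineno, fields in _tsv_rows(directory / "dt_edges.tsv"):
        if fields[0] == "drug_id":
            continue
        d, t = fields[0], fields[1]
        dt_edges.add((d, t))
        if len(fields) > 2 and fields[2] != "NA":
            dt_scores[(d, t)] = float(fields[2])
    tp_edges = set()
    for lineno, fields in _tsv_rows(directory / "tp_edges.tsv"):
        if fields[0] == "target_id":
            continue
        tp_edges.add((fields[0], fields[1]))
    return HeterogeneousNetwork(
        drugs=frozenset(header["drugs"]),
        targets=frozenset(header["targets"]),
        pathways=tuple(gene_sets),
        dt_edges=frozenset(dt_edges),
        tp_edges=frozenset(tp_edges),
        cs_threshold=float(header["cs_threshold"]),
        dt_scores=dt_scores,
    )


def write_similarity(matrix: SimilarityMatrix, path: str | Path) -> None:
    """Matrix as TSV (drug ids on both axes) plus a JSON sidecar with the
    method and provenance."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\t" + "\t".join(matrix.drug_ids) + "\n")
        for i, d in enumerate(matrix.drug_ids):
            fh.write(d + "\t" + "\t".join(fmt(v) for v in matrix.values[i]) + "\n")
    sidecar = {
        "method": matrix.method,
        "provenance": dict(matrix.provenance),
        "drug_ids": list(matrix.drug_ids),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_similarity(path: str | Path) -> SimilarityMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    method, provenance = "unknown", {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
        method = sidecar.get("method", method)
        provenance = sidecar.get("provenance", {})
    values = frame.to_numpy(dtype=float)
    # symmetrize away 6-digit rounding noise from the text round trip
    values = (values + values.T) / 2.0
    return SimilarityMatrix(
        drug_ids=tuple(str(c) for c in frame.columns),
        values=values,
        method=method,
        provenance=provenance,
    )


def read_de_table(path: str | Path) -> list[ExpressionRecord]:
    """DE table TSV: gene, fc (linear) or log2fc, fdr, optional contrast.

    The scale is declared by the column name — linear ``fc`` or signed
    ``log2fc`` — never inferred from the values.
    """
    rows = _tsv_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise TableFormatError(f"{path}: empty DE table") from None
    cols = [h.strip().lower() for h in header]
    if "gene" not in cols or "fdr" not in cols:
        raise TableFormatError(f"{path}:1: DE table needs 'gene' and 'fdr' columns")
    if "fc" in cols:
        fc_col, log_scale = cols.index("fc"), False
    elif "log2fc" in cols:
        fc_col, log_scale = cols.index("log2fc"), True
    else:
        raise TableFormatError(f"{path}:1: DE table needs an 'fc' or 'log2fc' column")
    gi, fi = cols.index("gene"), cols.index("fdr")
    ci = cols.index("contrast") if "contrast" in cols else None
    records = []
    for lineno, fields in rows:
        if len(fields) != len(cols):
            raise TableFormatError(f"{path}:{lineno}: expected {len(cols)} columns")
        try:
            fc = float(fields[fc_col])
            if log_scale:
                fc = float(2.0 ** fc)
            records.append(
                ExpressionRecord(
                    gene=fields[gi].strip().upper(),
                    fold_change=fc,
                    fdr=float(fields[fi]),
                    contrast=fields[ci].strip() if ci is not None else "",
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_de_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tfc\tfdr\tcontrast\n")
        for r in records:
            fh.write(f"{r.gene}\t{fmt(r.fold_change)}\t{fmt(r.fdr)}\t{r.contrast}\n")


def write_regulation_reports(
    reports: Iterable[RegulationReport], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "contrast\tpathway_id\tn_up\tn_down\tn_de\tratio_up\t"
            "denominator\tdenominator_policy\n"
        )
        for r in reports:
            ratio = fmt(r.ratio_up) if r.ratio_up is not None else "NA"
            fh.write(
                f"{r.contrast}\t{r.pathway_id}\t{r.n_up}\t{r.n_down}\t{r.n_de}\t"
                f"{ratio}\t{r.denominator}\t{r.denominator_policy}\n"
            )


def write_clusters(assignments: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tcluster\n")
        for drug in sorted(assignments):
            fh.write(f"{drug}\t{assignments[drug]}\n")


def write_subgraph(subgraph: MetapathSubgraph, edges_path: str | Path,
                   nodes_path: str | Path) -> None:
    """Edge list plus node-attribute table (target partition labels) for
    network viewers."""
    partition: dict[str, str] = {}
    edges: set[tuple[str, str, str]] = set()
    for share in subgraph.shares:
        for label, targets in (
            ("common", share.common),
            ("query_only", share.query_only),
            ("reference_only", share.reference_only),
        ):
            for t in targets:
                partition[t] = label
                if label in ("common", "query_only"):
                    edges.add((subgraph.query, t, "drug-target"))
                if label in ("common", "reference_only"):
                    edges.add((subgraph.reference, t, "drug-target"))
                edges.add((t, share.pathway_id, "target-pathway"))
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tedge_type\n")
        for src, dst, kind in sorted(edges):
            fh.write(f"{src}\t{dst}\t{kind}\n")
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write("node\tnode_type\tpartition\n")
        fh.write(f"{subgraph.query}\tdrug\tquery\n")
        fh.write(f"{subgraph.reference}\tdrug\treference\n")
        for t in sorted(partition):
            fh.write(f"{t}\ttarget\t{partition[t]}\n")
        for share in subgraph.shares:
            fh.write(f"{share.pathway_id}\tpathway\tshared\n")
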