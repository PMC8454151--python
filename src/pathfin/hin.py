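"""Drug-target evidence integration and heterogeneous-network assembly.

The network has three node types (drugs, targets, pathways) and two edge
semantics: drug-target interactions that survived a combined-confidence
threshold, and target-pathway membership edges. Per-source interaction
probabilities are fused with a noisy-OR combination before thresholding.
"""

from __future__ import annotations

import hashlib
import math
from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence, Set
from dataclasses import dataclass, field

__all__ = [
    "SourceEvidence",
    "DrugTargetInteraction",
    "GeneSet",
    "HeterogeneousNetwork",
    "map_bioassay_outcome",
    "combine_confidence",
    "score_interactions",
    "merge_composition_targets",
    "filter_interactions",
    "class_consensus_targets",
    "build_network",
    "restrict_pathways",
]

#: Bioassay outcome labels and the probability each maps to.
OUTCOME_PROBABILITIES: Mapping[str, float] = {
    "active": 1.0,
    "inactive": 0.0,
    "inconclusive": 0.5,
    "unspecific": 0.5,
    "unspecified": 0.5,
}


def map_bioassay_outcome(outcome: str) -> float:
    """Map a bioassay outcome label to an interaction probability.

    ``active`` -> 1.0, ``inactive`` -> 0.0, ``inconclusive`` (and its
    aliases ``unspecific``/``unspecified``) -> 0.5. Matching is
    case-insensitive; anything else raises ``ValueError``.
    """
    key = outcome.strip().lower()
    try:
        return OUTCOME_PROBABILITIES[key]
    except KeyError:
        raise ValueError(f"unknown bioassay outcome label: {outcome!r}") from None


def _check_probability(p: float, what: str) -> float:
    p = float(p)
    if math.isnan(p) or not 0.0 <= p <= 1.0:
        raise ValueError(f"{what} must lie in [0, 1], got {p!r}")
    return p


def combine_confidence(per_source: Mapping[str, float]) -> float:
    """Noisy-OR combination of per-source interaction probabilities.

    ``CS = 1 - prod_s (1 - P_s)``. Sources absent from the map contribute
    the identity factor (probability 0). The result is in [0, 1], is
    monotone non-decreasing in every input and equals 1 as soon as any
    source reports probability 1.
    """
    residual = 1.0
    for source, p in per_source.items():
        residual *= 1.0 - _check_probability(p, f"probability for source {source!r}")
    return 1.0 - residual


@dataclass(frozen=True)
class SourceEvidence:
    """One (drug, target, source, probability) record from an evidence channel."""

    drug_id: str
    target_id: str
    source: str
    probability: float

    def __post_init__(self) -> None:
        _check_probability(self.probability, "probability")


@dataclass(frozen=True)
class DrugTargetInteraction:
    """A drug-target interaction with its combined confidence score."""

    drug_id: str
    target_id: str
    combined_score: float
    contributing_sources: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        _check_probability(self.combined_score, "combined_score")


def score_interactions(evidence: Iterable[SourceEvidence]) -> list[DrugTargetInteraction]:
    """Collapse per-source evidence into one scored interaction per (drug, target).

    Duplicate records for the same (drug, target, source) are resolved by
    keeping the maximum probability within that source before combining.
    """
    per_pair: dict[tuple[str, str], dict[str, float]] = defaultdict(dict)
    for rec in evidence:
        key = (rec.drug_id, rec.target_id)
        prev = per_pair[key].get(rec.source)
        if prev is None or rec.probability > prev:
            per_pair[key][rec.source] = rec.probability
    out = []
    for (drug, target), sources in sorted(per_pair.items()):
        out.append(
            DrugTargetInteraction(
                drug_id=drug,
                target_id=target,
                combined_score=combine_confidence(sources),
                contributing_sources=frozenset(sources),
            )
        )
    return out


def merge_composition_targets(
    per_composition: Sequence[Iterable[DrugTargetInteraction]],
    drug_id: str | None = None,
) -> list[DrugTargetInteraction]:
    """Merge interaction sets of a multi-composition drug into one set.

    When several compositions hit the same target, the largest combined
    score wins and contributing sources are unioned. ``drug_id`` names the
    merged drug; if omitted the first interaction's drug id is reused.
    """
    if len(per_composition) == 0:
        raise ValueError("merge_composition_targets requires at least one composition")
    best: dict[str, tuple[float, frozenset[str]]] = {}
    for interactions in per_composition:
        for it in interactions:
            if drug_id is None:
                drug_id = it.drug_id
            score, sources = best.get(it.target_id, (-1.0, frozenset()))
            best[it.target_id] = (
                max(score, it.combined_score),
                sources | it.contributing_sources,
            )
    return [
        DrugTargetInteraction(drug_id or "", target, score, sources)
        for target, (score, sources) in sorted(best.items())
    ]


def filter_interactions(
    interactions: Iterable[DrugTargetInteraction], threshold: float = 0.4
) -> list[DrugTargetInteraction]:
    """Retain interactions with combined score strictly above ``threshold``."""
    threshold = _check_probability(threshold, "threshold")
    return [it for it in interactions if it.combined_score > threshold]


def class_consensus_targets(
    targets_by_drug: Mapping[str, Set[str]], min_support: int = 2
) -> set[str]:
    """Targets hit by at least ``min_support`` drugs of a class."""
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    counts: dict[str, int] = defaultdict(int)
    for targets in targets_by_drug.values():
        for t in set(targets):
            counts[t] += 1
    return {t for t, c in counts.items() if c >= min_support}


@dataclass(frozen=True)
class GeneSet:
    """A named pathway gene set (GMT record)."""

    pathway_id: str
    name: str
    genes: frozenset[str]
    collection: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.pathway_id!r} has no genes")


@dataclass(frozen=True)
class HeterogeneousNetwork:
    """Drug-target-pathway network after confidence thresholding.

    ``dt_edges`` are unweighted (drug, target) pairs; the combined score is
    kept only as metadata in ``dt_scores``. ``tp_edges`` are (target,
    pathway_id) membership pairs; by default they are restricted to genes
    that are a target of at least one drug, which leaves all metapath
    counts unchanged.
    """

    drugs: frozenset[str]
    targets: frozenset[str]
    pathways: tuple[GeneSet, ...]
    dt_edges: frozenset[tuple[str, str]]
    tp_edges: frozenset[tuple[str, str]]
    cs_threshold: float
    dt_scores: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pathway_ids = {p.pathway_id for p in self.pathways}
        if len(pathway_ids) != len(self.pathways):
            raise ValueError("duplicate pathway ids in network")
        for d, t in self.dt_edges:
            if d not in self.drugs or t not in self.targets:
                raise ValueError(f"dt edge ({d!r}, {t!r}) has an endpoint outside the network")
        for g, p in self.tp_edges:
            if p not in pathway_ids:
                raise ValueError(f"tp edge references unknown pathway {p!r}")

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]

    def pathway(self, pathway_id: str) -> GeneSet:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def targets_of(self, drug: str) -> set[str]:
        if drug not in self.drugs:
            raise KeyError(f"unknown drug {drug!r}")
        return {t for d, t in self.dt_edges if d == drug}

    def pathway_members(self, pathway_id: str) -> set[str]:
        """Genes of a pathway that carry a tp edge (metapath-relevant members)."""
        if pathway_id not in set(self.pathway_ids):
            raise KeyError(f"unknown pathway {pathway_id!r}")
        return {g for g, p in self.tp_edges if p == pathway_id}

    def content_hash(self) -> str:
        """Stable hash of the edge structure, used for provenance stamps."""
        h = hashlib.sha256()
        for edge in sorted(self.dt_edges):
            h.update(("DT\t" + "\t".join(edge) + "\n").encode())
        for edge in sorted(self.tp_edges):
            h.update(("TP\t" + "\t".join(edge) + "\n").encode())
        h.update(f"cs={self.cs_threshold!r}".encode())
        return h.hexdigest()[:16]


def build_network(
    interactions: Iterable[DrugTargetInteraction],
    gene_sets: Sequence[GeneSet],
    cs_threshold: float = 0.4,
    restrict_tp: bool = True,
    keep_drugs: Iterable[str] = (),
) -> HeterogeneousNetwork:
    """Assemble the heterogeneous network from scored interactions and gene sets.

    Interactions are filtered at ``cs_threshold`` (strict). With
    ``restrict_tp`` (default) only genes that are a target of some drug get
    tp edges; non-target genes cannot mediate any metapath instance, so
    fingerprints are unaffected. ``keep_drugs`` forces drugs into the node
    set even when none of their interactions survive the filter.
    """
    kept = filter_interactions(interactions, cs_threshold)
    if not kept:
        raise ValueError(
            f"no drug-target interactions with combined score > {cs_threshold}; "
            "network would have no dt edges"
        )
    dt_edges = frozenset((it.drug_id, it.target_id) for it in kept)
    dt_scores = {(it.drug_id, it.target_id): it.combined_score for it in kept}
    drugs = frozenset(it.drug_id for it in kept) | frozenset(keep_drugs)
    targets = frozenset(it.target_id for it in kept)
    tp_edges = set()
    for gs in gene_sets:
        members = gs.genes & targets if restrict_tp else gs.genes
        tp_edges.update((g, gs.pathway_id) for g in members)
    return HeterogeneousNetwork(
        drugs=drugs,
        targets=targets if restrict_tp else targets | {g for g, _ in tp_edges},
        pathways=tuple(gene_sets),
        dt_edges=dt_edges,
        tp_edges=frozenset(tp_edges),
        cs_threshold=cs_threshold,
        dt_scores=dt_scores,
    )


def restrict_pathways(
    network: HeterogeneousNetwork, selection: str | Iterable[str]
) -> HeterogeneousNetwork:
    """Sub-network keeping only selected pathways (dt edges unchanged).

    ``selection`` is either a case-insensitive substring matched against
    pathway names, or an explicit collection of pathway ids. An empty or
    unmatched selection is an error.
    """
    if isinstance(selection, str):
        needle = selection.strip().lower()
        if not needle:
            raise ValueError("empty pathway keyword")
        keep = [p for p in network.pathways if needle in p.name.lower()]
        if not keep:
            raise ValueError(f"keyword {selection!r} matches no pathway name")
    else:
        wanted = set(selection)
        if not wanted:
            raise ValueError("empty pathway id selection")
        known = set(network.pathway_ids)
        missing = wanted - known
        if missing:
            raise ValueError(f"unknown pathway ids: {sorted(missing)}")
        keep = [p for p in network.pathways if p.pathway_id in wanted]
    keep_ids = {p.pathway_id for p in keep}
    return HeterogeneousNetwork(
        drugs=network.drugs,
        targets=network.targets,
        pathways=tuple(keep),
        dt_edges=network.dt_edges,
        tp_edges=frozenset(e for e in network.tp_edges if e[1] in keep_ids),
        cs_threshold=network.cs_threshold,
        dt_scores=network.dt_scores,
    )
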