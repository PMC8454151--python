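"""Synthetic fixtures: planted-structure networks, multi-source evidence
tables and differential-expression tables.

The planted network contains drug groups that share targets within the
group and pathways built around each group's target pool, plus an optional
"confounder" drug whose targets come from one donor group while those
targets' pathway memberships follow a second donor group. Target-profile
similarity therefore pulls the confounder toward the target donor, while
metapath (pathway-fingerprint) similarity pulls it toward the pathway
donor — a recoverable dissociation used throughout the test suite.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np

from .hin import (
    DrugTargetInteraction,
    GeneSet,
    HeterogeneousNetwork,
    SourceEvidence,
    build_network,
)

__all__ = [
    "PlantedDesign",
    "GroupTruth",
    "generate_planted_network",
    "generate_source_evidence",
    "generate_expression_table",
]

CONFOUNDER_ID = "DX"


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of the planted-structure generator."""

    seed: int = 0
    n_groups: int = 2
    drugs_per_group: int = 3
    targets_per_drug: int = 6
    pathways_per_group: int = 4
    within_group_share: float = 1.0  # fraction of each drug's targets in the group core
    confounder: tuple[int, int] | None = (0, 1)  # (target donor, pathway donor)
    bridge_targets: int = 2  # confounder target count, taken from the donor core
    filler_genes_per_pathway: int = 3  # pathway genes never targeted by any drug
    edge_noise: float = 0.0  # drop/spurious rate on dt edges

    def __post_init__(self) -> None:
        if min(self.n_groups, self.drugs_per_group, self.targets_per_drug,
               self.pathways_per_group) < 1:
            raise ValueError("all design counts must be >= 1")
        if not 0.0 <= self.edge_noise < 1.0:
            raise ValueError("edge_noise must lie in [0, 1)")
        if not 0.0 < self.within_group_share <= 1.0:
            raise ValueError("within_group_share must lie in (0, 1]")
        if self.confounder is not None:
            td, pd_ = self.confounder
            if td == pd_ or not (0 <= td < self.n_groups and 0 <= pd_ < self.n_groups):
                raise ValueError(
                    "confounder needs two distinct donor groups inside range"
                )
            core = max(1, round(self.within_group_share * self.targets_per_drug))
            if not 1 <= self.bridge_targets <= core:
                raise ValueError(
                    "bridge_targets must be between 1 and the group core size"
                )


@dataclass(frozen=True)
class GroupTruth:
    """Ground-truth group labels for one drug (the two differ only for the
    confounder)."""

    target_group: int
    pathway_group: int


def _group_layout(design: PlantedDesign):
    m = design.targets_per_drug
    core_size = max(1, round(design.within_group_share * m))
    n_private = m - core_size
    cores = {
        g: [f"T{g}_C{i}" for i in range(core_size)] for g in range(design.n_groups)
    }
    privates = {
        (g, d): [f"T{g}_D{d}_P{i}" for i in range(n_private)]
        for g in range(design.n_groups)
        for d in range(design.drugs_per_group)
    }
    return cores, privates


def generate_planted_network(
    design: PlantedDesign,
) -> tuple[HeterogeneousNetwork, dict[str, GroupTruth]]:
    """Build the planted network and its ground-truth labels.

    Deterministic given ``design.seed``; noise perturbs dt edges only
    (each true edge dropped with probability ``edge_noise``, and each drug
    gains spurious targets at the same rate).
    """
    rng = np.random.default_rng(design.seed)
    cores, privates = _group_layout(design)

    drug_targets: dict[str, set[str]] = {}
    truth: dict[str, GroupTruth] = {}
    for g in range(design.n_groups):
        for d in range(design.drugs_per_group):
            drug = f"D{g}_{d}"
            drug_targets[drug] = set(cores[g]) | set(privates[(g, d)])
            truth[drug] = GroupTruth(target_group=g, pathway_group=g)

    bridge: set[str] = set()
    if design.confounder is not None:
        t_donor, p_donor = design.confounder
        bridge = set(cores[t_donor][: design.bridge_targets])
        drug_targets[CONFOUNDER_ID] = set(bridge)
        truth[CONFOUNDER_ID] = GroupTruth(target_group=t_donor, pathway_group=p_donor)

    # Pathway gene pools: the group's full target pool, minus the bridge for
    # the target donor and plus the bridge for the pathway donor, so the
    # confounder's fingerprint lives entirely in the pathway donor's sets.
    pools: dict[int, set[str]] = {}
    for g in range(design.n_groups):
        pool = set(cores[g])
        for d in range(design.drugs_per_group):
            pool |= set(privates[(g, d)])
        pools[g] = pool
    if design.confounder is not None:
        t_donor, p_donor = design.confounder
        pools[t_donor] -= bridge
        pools[p_donor] |= bridge

    gene_sets = []
    for g in range(design.n_groups):
        fillers = [f"G{g}_F{i}" for i in range(design.filler_genes_per_pathway)]
        for p in range(design.pathways_per_group):
            gene_sets.append(
                GeneSet(
                    pathway_id=f"P{g}_{p}",
                    name=f"group {g} pathway {p}",
                    genes=frozenset(pools[g]) | frozenset(fillers),
                    collection="synthetic",
                )
            )

    all_targets = sorted(set().union(*drug_targets.values()))
    if design.edge_noise > 0:
        for drug in sorted(drug_targets):
            kept = {
                t for t in sorted(drug_targets[drug])
                if rng.random() >= design.edge_noise
            }
            n_spurious = rng.binomial(design.targets_per_drug, design.edge_noise)
            candidates = [t for t in all_targets if t not in drug_targets[drug]]
            if candidates and n_spurious:
                kept |= set(
                    rng.choice(candidates, size=min(n_spurious, len(candidates)),
                               replace=False)
                )
            drug_targets[drug] = kept

    interactions = [
        DrugTargetInteraction(drug, target, 1.0, frozenset({"planted"}))
        for drug in sorted(drug_targets)
        for target in sorted(drug_targets[drug])
    ]
    if not interactions:
        raise ValueError("noise removed every planted edge; lower edge_noise")
    network = build_network(
        interactions, gene_sets, cs_threshold=0.4, keep_drugs=drug_targets
    )
    return network, truth


def generate_source_evidence(
    network: HeterogeneousNetwork,
    detection: Mapping[str, float] | None = None,
    seed: int = 0,
    spurious_rate: float = 0.0,
) -> list[SourceEvidence]:
    """Emit per-source evidence records that regenerate ``network``'s dt edges.

    Each true edge emits each source's record independently with that
    source's detection probability, carrying a probability drawn uniformly
    from [0.5, 1.0] (so single-source edges survive the 0.4 combined-score
    threshold). Spurious records target random non-edges at
    ``spurious_rate`` per true edge per source, with probabilities uniform
    on [0.0, 0.5).
    """
    if detection is None:
        detection = {"stitch": 1.0, "pubchem": 1.0, "batman": 1.0}
    for source, p in detection.items():
        if not 0.0 < p <= 1.0:
            raise ValueError(f"detection probability for {source!r} must be in (0, 1]")
    if not 0.0 <= spurious_rate < 1.0:
        raise ValueError("spurious_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    true_edges = sorted(network.dt_edges)
    non_edges = [
        (d, t)
        for d in sorted(network.drugs)
        for t in sorted(network.targets)
        if (d, t) not in network.dt_edges
    ]
    records: list[SourceEvidence] = []
    for source in sorted(detection):
        det = detection[source]
        for drug, target in true_edges:
            if rng.random() < det:
                records.append(
                    SourceEvidence(drug, target, source, float(rng.uniform(0.5, 1.0)))
                )
        n_spurious = rng.binomial(len(true_edges), spurious_rate)
        if non_edges and n_spurious:
            picks = rng.choice(len(non_edges), size=min(n_spurious, len(non_edges)),
                               replace=False)
            for i in sorted(picks):
                drug, target = non_edges[i]
                records.append(
                    SourceEvidence(drug, target, source, float(rng.uniform(0.0, 0.5)))
                )
    return records


def generate_expression_table(
    network: HeterogeneousNetwork,
    direction: Mapping[str, str],
    effect_fc: float = 3.0,
    n_noise_genes: int = 100,
    seed: int = 0,
    contrast: str = "drug_vs_model",
) -> list["ExpressionRecord"]:
    """DE summary table with planted per-pathway regulation direction.

    Genes of up-planted pathways get fold changes near ``effect_fc`` with
    small FDR; down-planted near ``1/effect_fc``; noise genes hover around
    FC 1 with large FDR. A gene in several planted pathways follows the
    first pathway in sorted-id order.
    """
    from .moa import ExpressionRecord

    if effect_fc <= 1.0:
        raise ValueError("effect_fc must be > 1")
    known = set(network.pathway_ids)
    for pid, d in direction.items():
        if pid not in known:
            raise ValueError(f"pathway {pid!r} not in network")
        if d not in ("up", "down"):
            raise ValueError(f"direction for {pid!r} must be 'up' or 'down'")
    rng = np.random.default_rng(seed)
    planted: dict[str, str] = {}
    for pid in sorted(direction):
        for gene in sorted(network.pathway(pid).genes):
            planted.setdefault(gene, direction[pid])
    records = []
    for gene in sorted(planted):
        fc = effect_fc * float(np.exp(rng.normal(0.0, 0.05)))
        if planted[gene] == "down":
            fc = 1.0 / fc
        records.append(
            ExpressionRecord(gene, fc, float(rng.uniform(0.001, 0.05)), contrast)
        )
    for i in range(n_noise_genes):
        records.append(
            ExpressionRecord(
                f"NOISE{i}",
                float(np.exp(rng.normal(0.0, 0.1))),
                float(rng.uniform(0.2, 1.0)),
                contrast,
            )
        )
    return records
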