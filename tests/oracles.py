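"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the package's fingerprint/inner-product code
paths: path instances are counted by exhaustive enumeration of 4-edge
walks, and random networks are built edge-by-edge.
"""

from __future__ import annotations

import numpy as np

from pathfin.hin import GeneSet, HeterogeneousNetwork


def enumerate_path_instances(net: HeterogeneousNetwork, x: str, y: str) -> int:
    """Count metapath walks x -> t1 -> p <- t2 <- y by brute force."""
    count = 0
    for t1 in sorted(net.targets):
        if (x, t1) not in net.dt_edges:
            continue
        for gs in net.pathways:
            if (t1, gs.pathway_id) not in net.tp_edges:
                continue
            for t2 in sorted(net.targets):
                if (t2, gs.pathway_id) in net.tp_edges and (y, t2) in net.dt_edges:
                    count += 1
    return count


def pathsim_from_enumeration(net: HeterogeneousNetwork, x: str, y: str) -> float:
    cxy = enumerate_path_instances(net, x, y)
    denom = enumerate_path_instances(net, x, x) + enumerate_path_instances(net, y, y)
    return 2.0 * cxy / denom if denom else 0.0


def random_network(
    rng: np.random.Generator,
    max_drugs: int = 8,
    max_targets: int = 25,
    max_pathways: int = 8,
    dt_density: float = 0.3,
    tp_density: float = 0.3,
) -> HeterogeneousNetwork:
    """Random incidence network built directly from edge sets."""
    n_drugs = int(rng.integers(1, max_drugs + 1))
    n_targets = int(rng.integers(1, max_targets + 1))
    n_pathways = int(rng.integers(1, max_pathways + 1))
    drugs = [f"d{i}" for i in range(n_drugs)]
    targets = [f"t{i}" for i in range(n_targets)]
    dt = {
        (d, t) for d in drugs for t in targets if rng.random() < dt_density
    }
    gene_sets = []
    tp = set()
    for j in range(n_pathways):
        members = frozenset(t for t in targets if rng.random() < tp_density)
        # GMT records cannot be empty; guarantee one member
        if not members:
            members = frozenset({targets[int(rng.integers(n_targets))]})
        gene_sets.append(GeneSet(f"p{j}", f"pathway {j}", members))
        tp.update((t, f"p{j}") for t in members)
    return HeterogeneousNetwork(
        drugs=frozenset(drugs),
        targets=frozenset(targets),
        pathways=tuple(gene_sets),
        dt_edges=frozenset(dt),
        tp_edges=frozenset(tp),
        cs_threshold=0.4,
    )
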