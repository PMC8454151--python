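"""Drug-drug similarity: target-profile Jaccard and metapath PathSim.

PathSim counts instances of the metapath drug -> target -> pathway <-
target <- drug. The per-drug pathway fingerprint F_x[p] = |T_x ∩
members(p)| makes the count between drugs x and y the inner product
F_x · F_y, so the whole matrix is one integer matrix product.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence, Set
from dataclasses import dataclass, field

import numpy as np

from .hin import HeterogeneousNetwork

__all__ = [
    "DegenerateDrugWarning",
    "PathwayFingerprint",
    "SimilarityMatrix",
    "pathway_fingerprints",
    "count_path_instances",
    "pathsim",
    "pathsim_matrix",
    "target_jaccard",
    "target_similarity_matrix",
]


class DegenerateDrugWarning(UserWarning):
    """A drug with no targets (or no target in any pathway) was scored as 0."""


@dataclass(frozen=True)
class PathwayFingerprint:
    """Per-drug vector of target counts inside each pathway."""

    drug_id: str
    counts: Mapping[str, int]

    def self_instances(self) -> int:
        return sum(c * c for c in self.counts.values())


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric drug-by-drug similarity with method provenance."""

    drug_ids: tuple[str, ...]
    values: np.ndarray
    method: str
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.drug_ids), len(self.drug_ids)):
            raise ValueError("similarity matrix shape does not match drug ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix is not symmetric")
        object.__setattr__(self, "values", v)

    def index(self, drug: str) -> int:
        try:
            return self.drug_ids.index(drug)
        except ValueError:
            raise KeyError(f"unknown drug {drug!r}") from None

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])


def fingerprint_matrix(
    network: HeterogeneousNetwork, drug_ids: Sequence[str] | None = None
) -> tuple[list[str], list[str], np.ndarray]:
    """Integer matrix F with F[i, j] = |targets(drug_i) ∩ members(pathway_j)|."""
    drugs = sorted(network.drugs) if drug_ids is None else list(drug_ids)
    pathway_ids = network.pathway_ids
    members = {pid: network.pathway_members(pid) for pid in pathway_ids}
    F = np.zeros((len(drugs), len(pathway_ids)), dtype=np.int64)
    for i, d in enumerate(drugs):
        t = network.targets_of(d)
        for j, pid in enumerate(pathway_ids):
            F[i, j] = len(t & members[pid])
    return drugs, pathway_ids, F


def pathway_fingerprints(network: HeterogeneousNetwork) -> dict[str, PathwayFingerprint]:
    drugs, pathway_ids, F = fingerprint_matrix(network)
    return {
        d: PathwayFingerprint(d, dict(zip(pathway_ids, map(int, F[i]))))
        for i, d in enumerate(drugs)
    }


def count_path_instances(network: HeterogeneousNetwork, x: str, y: str) -> int:
    """Exact number of metapath instances x -> t1 -> p <- t2 <- y.

    t1 = t2 (a walk through one shared target) is a valid instance. Equals
    the fingerprint inner product sum_p F_x[p] * F_y[p].
    """
    _, _, F = fingerprint_matrix(network, [x, y])
    return int(F[0] @ F[1])


def pathsim(network: HeterogeneousNetwork, x: str, y: str) -> float:
    """PathSim score 2*c(x,y) / (c(x,x) + c(y,y)) in [0, 1].

    Drugs with zero self path instances get score 0 (with a
    ``DegenerateDrugWarning``), including against themselves.
    """
    _, _, F = fingerprint_matrix(network, [x, y])
    cxy = int(F[0] @ F[1])
    denom = int(F[0] @ F[0]) + int(F[1] @ F[1])
    if denom == 0:
        warnings.warn(
            f"drugs {x!r}/{y!r} have no metapath instances; pathsim set to 0",
            DegenerateDrugWarning,
            stacklevel=2,
        )
        return 0.0
    return 2.0 * cxy / denom


def pathsim_matrix(network: HeterogeneousNetwork) -> SimilarityMatrix:
    """All pairwise PathSim scores via the fingerprint inner-product form."""
    drugs, _, F = fingerprint_matrix(network)
    C = (F @ F.T).astype(float)
    self_counts = np.diag(C).copy()
    denom = self_counts[:, None] + self_counts[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(denom > 0, 2.0 * C / np.where(denom > 0, denom, 1.0), 0.0)
    if np.any(self_counts == 0):
        bad = [d for d, c in zip(drugs, self_counts) if c == 0]
        warnings.warn(
            f"degenerate drugs with no metapath instances: {bad}",
            DegenerateDrugWarning,
            stacklevel=2,
        )
    return SimilarityMatrix(
        drug_ids=tuple(drugs),
        values=S,
        method="pathsim",
        provenance={
            "network_hash": network.content_hash(),
            "cs_threshold": network.cs_threshold,
        },
    )


def target_jaccard(t_a: Set[str], t_b: Set[str]) -> float:
    """Jaccard similarity |A ∩ B| / |A ∪ B| of two target sets.

    Two empty sets score 0 (with a warning) rather than raising.
    """
    union = len(set(t_a) | set(t_b))
    if union == 0:
        warnings.warn(
            "both target sets empty; jaccard set to 0",
            DegenerateDrugWarning,
            stacklevel=2,
        )
        return 0.0
    return len(set(t_a) & set(t_b)) / union


def target_similarity_matrix(
    source: HeterogeneousNetwork | Mapping[str, Set[str]],
) -> SimilarityMatrix:
    """Pairwise target-profile Jaccard over a network or a drug->targets map."""
    if isinstance(source, HeterogeneousNetwork):
        targets = {d: source.targets_of(d) for d in sorted(source.drugs)}
        provenance: dict[str, object] = {
            "network_hash": source.content_hash(),
            "cs_threshold": source.cs_threshold,
        }
    else:
        targets = {d: set(ts) for d, ts in sorted(source.items())}
        provenance = {}
    drugs = list(targets)
    if len(drugs) < 2:
        raise ValueError("target similarity needs at least 2 drugs")
    S = np.zeros((len(drugs), len(drugs)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateDrugWarning)
        for i, a in enumerate(drugs):
            for j in range(i, len(drugs)):
                S[i, j] = S[j, i] = target_jaccard(targets[a], targets[drugs[j]])
    empties = [d for d in drugs if not targets[d]]
    if empties:
        warnings.warn(
            f"drugs with empty target sets: {empties}", DegenerateDrugWarning, stacklevel=2
        )
    return SimilarityMatrix(
        drug_ids=tuple(drugs), values=S, method="target_jaccard", provenance=provenance
    )
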