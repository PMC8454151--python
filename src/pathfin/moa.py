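"""Mechanism-of-action inference: shared metapath subgraphs between a query
drug and a reference, pathway association ranking, and regulation-direction
scoring from differential-expression tables."""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

from .hin import GeneSet, HeterogeneousNetwork

__all__ = [
    "ExpressionRecord",
    "RegulationReport",
    "PathwayShare",
    "MetapathSubgraph",
    "shared_pathway_subgraph",
    "predict_pathways",
    "classify_de",
    "regulation_ratio",
    "compare_regulation",
]

UP, DOWN, NS = "up", "down", "ns"


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's differential-expression result for a contrast.

    ``fold_change`` is on the linear scale (>0); log2 input is converted at
    the I/O layer based on a declared column name, never by value sniffing.
    """

    gene: str
    fold_change: float
    fdr: float
    contrast: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.fold_change) or self.fold_change <= 0:
            raise ValueError(f"fold change must be finite and positive, got {self.fold_change!r}")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"FDR must lie in [0, 1], got {self.fdr!r}")


def classify_de(
    records: Iterable[ExpressionRecord],
    fdr_cutoff: float = 0.1,
    fc_cutoff: float = 1.5,
) -> dict[str, str]:
    """Assign each gene to up / down / ns with inclusive boundaries.

    up: FDR <= fdr_cutoff and FC >= fc_cutoff; down: FDR <= fdr_cutoff and
    FC <= 1/fc_cutoff; everything else ns. Duplicate genes within a
    contrast are rejected.
    """
    if fc_cutoff <= 0:
        raise ValueError("fc_cutoff must be positive")
    calls: dict[str, str] = {}
    for rec in records:
        if rec.gene in calls:
            raise ValueError(f"duplicate gene {rec.gene!r} in contrast")
        if rec.fdr <= fdr_cutoff and rec.fold_change >= fc_cutoff:
            calls[rec.gene] = UP
        elif rec.fdr <= fdr_cutoff and rec.fold_change <= 1.0 / fc_cutoff:
            calls[rec.gene] = DOWN
        else:
            calls[rec.gene] = NS
    return calls


@dataclass(frozen=True)
class RegulationReport:
    """Up/down counts and up-regulated ratio for one (contrast, pathway)."""

    contrast: str
    pathway_id: str
    n_up: int
    n_down: int
    ratio_up: float | None
    denominator: int
    denominator_policy: str

    @property
    def n_de(self) -> int:
        return self.n_up + self.n_down


def regulation_ratio(
    de_calls: Mapping[str, str],
    gene_set: GeneSet,
    contrast: str = "",
    policy: str = "de",
) -> RegulationReport:
    """Fraction of up-regulated genes in a pathway after treatment.

    ``policy`` selects the denominator: ``"de"`` (default) uses the DE
    genes in the pathway (n_up + n_down); ``"measured"`` uses all genes of
    the pathway present in the DE table. A zero denominator yields a
    missing ratio with zeroed counts preserved.
    """
    if policy not in ("de", "measured"):
        raise ValueError(f"unknown denominator policy {policy!r}")
    in_set = {g: c for g, c in de_calls.items() if g in gene_set.genes}
    n_up = sum(1 for c in in_set.values() if c == UP)
    n_down = sum(1 for c in in_set.values() if c == DOWN)
    denominator = n_up + n_down if policy == "de" else len(in_set)
    ratio = n_up / denominator if denominator > 0 else None
    return RegulationReport(
        contrast=contrast,
        pathway_id=gene_set.pathway_id,
        n_up=n_up,
        n_down=n_down,
        ratio_up=ratio,
        denominator=denominator,
        denominator_policy=policy,
    )


def compare_regulation(
    report_a: RegulationReport,
    report_b: RegulationReport,
    neutral_band: tuple[float, float] = (0.4, 0.6),
) -> str:
    """Classify two reports for the same pathway as concordant / discordant /
    indeterminate.

    A ratio strictly above the band is "up", strictly below is "down";
    ratios inside the band (inclusive) or missing give "indeterminate".
    """
    if report_a.pathway_id != report_b.pathway_id:
        raise ValueError(
            f"pathway mismatch: {report_a.pathway_id!r} vs {report_b.pathway_id!r}"
        )
    lo, hi = neutral_band
    if not 0 <= lo <= hi <= 1:
        raise ValueError(f"invalid neutral band {neutral_band!r}")

    def side(r: float | None) -> str | None:
        if r is None or lo <= r <= hi:
            return None
        return UP if r > hi else DOWN

    sa, sb = side(report_a.ratio_up), side(report_b.ratio_up)
    if sa is None or sb is None:
        return "indeterminate"
    return "concordant" if sa == sb else "discordant"


@dataclass(frozen=True)
class PathwayShare:
    """One shared pathway of a (query, reference) pair.

    Targets mediating metapath instances through the pathway are
    partitioned into common / query-only / reference-only; the pair's path
    instances through this pathway number |T_q| * |T_r|.
    """

    pathway_id: str
    common: frozenset[str]
    query_only: frozenset[str]
    reference_only: frozenset[str]
    contribution: int


@dataclass(frozen=True)
class MetapathSubgraph:
    query: str
    reference: str
    shares: tuple[PathwayShare, ...]

    @property
    def total_instances(self) -> int:
        return sum(s.contribution for s in self.shares)


def shared_pathway_subgraph(
    network: HeterogeneousNetwork, query: str, reference: str
) -> MetapathSubgraph:
    """Extract the pathways through which query and reference share metapaths.

    Includes every pathway where both drugs have at least one member
    target; contributions sum to the pair's total path-instance count.
    """
    tq = network.targets_of(query)
    tr = network.targets_of(reference)
    shares = []
    for pid in network.pathway_ids:
        members = network.pathway_members(pid)
        q_in = tq & members
        r_in = tr & members
        if q_in and r_in:
            shares.append(
                PathwayShare(
                    pathway_id=pid,
                    common=frozenset(q_in & r_in),
                    query_only=frozenset(q_in - r_in),
                    reference_only=frozenset(r_in - q_in),
                    contribution=len(q_in) * len(r_in),
                )
            )
    if not shares:
        warnings.warn(
            f"no shared metapath instances between {query!r} and {reference!r}",
            UserWarning,
            stacklevel=2,
        )
    return MetapathSubgraph(query=query, reference=reference, shares=tuple(shares))


def predict_pathways(
    network: HeterogeneousNetwork,
    query: str,
    reference: str,
    top_n: int | None = None,
) -> list[tuple[str, int]]:
    """Shared pathways ranked by descending path-instance contribution.

    Ties break on pathway id for determinism.
    """
    subgraph = shared_pathway_subgraph(network, query, reference)
    ranked = sorted(subgraph.shares, key=lambda s: (-s.contribution, s.pathway_id))
    if top_n is not None:
        ranked = ranked[:top_n]
    return [(s.pathway_id, s.contribution) for s in ranked]
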