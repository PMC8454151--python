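import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pathfin.hin import (
    DrugTargetInteraction,
    GeneSet,
    SourceEvidence,
    build_network,
    class_consensus_targets,
    combine_confidence,
    filter_interactions,
    map_bioassay_outcome,
    merge_composition_targets,
    restrict_pathways,
    score_interactions,
)


class TestMapBioassayOutcome:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("active", 1.0),
            ("inactive", 0.0),
            ("inconclusive", 0.5),
            ("unspecific", 0.5),
            ("unspecified", 0.5),
            ("Active", 1.0),
            ("  INACTIVE ", 0.0),
        ],
    )
    def test_mapping(self, label, expected):
        assert map_bioassay_outcome(label) == expected

    def test_unknown_label_reports_offender(self):
        with pytest.raises(ValueError, match="bogus"):
            map_bioassay_outcome("bogus")


class TestCombineConfidence:
    def test_hand_value(self):
        # 1 - 0.7 * 0.5 * 0.8
        assert combine_confidence(
            {"stitch": 0.3, "pubchem": 0.5, "batman": 0.2}
        ) == pytest.approx(0.72, abs=1e-12)

    def test_certain_source_absorbs(self):
        assert combine_confidence({"stitch": 1.0}) == 1.0
        assert combine_confidence({"stitch": 1.0, "pubchem": 0.123}) == 1.0

    def test_empty_evidence(self):
        assert combine_confidence({}) == 0.0

    def test_zero_iff_all_zero(self):
        assert combine_confidence({"a": 0.0, "b": 0.0}) == 0.0
        assert combine_confidence({"a": 0.0, "b": 0.01}) > 0.0

    @pytest.mark.parametrize("bad", [-0.1, 1.1, float("nan")])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            combine_confidence({"stitch": bad})

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_bounds(self, probs):
        cs = combine_confidence({f"s{i}": p for i, p in enumerate(probs)})
        assert 0.0 <= cs <= 1.0
        assert cs >= max(probs) - 1e-12

    @given(
        st.dictionaries(st.sampled_from("abcdef"), st.floats(0, 1), min_size=1),
        st.floats(0.001, 1),
    )
    def test_noisy_or_monotone(self, per_source, extra):
        base = combine_confidence(per_source)
        assert combine_confidence({**per_source, "extra": extra}) >= base - 1e-12

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=6), st.randoms())
    def test_permutation_invariant(self, probs, rnd):
        keys = [f"s{i}" for i in range(len(probs))]
        shuffled = list(zip(keys, probs))
        rnd.shuffle(shuffled)
        a = combine_confidence(dict(zip(keys, probs)))
        b = combine_confidence(dict(shuffled))
        assert a == pytest.approx(b, abs=1e-12)


class TestScoreInteractions:
    def test_duplicate_source_rows_keep_max(self):
        evidence = [
            SourceEvidence("d", "T", "stitch", 0.2),
            SourceEvidence("d", "T", "stitch", 0.6),
        ]
        (it,) = score_interactions(evidence)
        assert it.combined_score == pytest.approx(0.6)
        assert it.contributing_sources == {"stitch"}

    def test_multi_source_combination(self):
        evidence = [
            SourceEvidence("d", "T", "stitch", 0.3),
            SourceEvidence("d", "T", "pubchem", 0.5),
            SourceEvidence("d", "T", "batman", 0.2),
        ]
        (it,) = score_interactions(evidence)
        assert it.combined_score == pytest.approx(0.72, abs=1e-12)
        assert it.contributing_sources == {"stitch", "pubchem", "batman"}


class TestMergeCompositionTargets:
    def _mk(self, scores):
        return [DrugTargetInteraction("c", t, s) for t, s in scores.items()]

    def test_max_rule(self):
        merged = merge_composition_targets(
            [self._mk({"T1": 0.5}), self._mk({"T1": 0.8})], drug_id="X"
        )
        assert {(m.target_id, m.combined_score) for m in merged} == {("T1", 0.8)}

    def test_single_composition_identity(self):
        merged = merge_composition_targets([self._mk({"T1": 0.5})], drug_id="X")
        assert [(m.target_id, m.combined_score) for m in merged] == [("T1", 0.5)]

    def test_elementwise_max_over_union(self):
        merged = merge_composition_targets(
            [self._mk({"T1": 0.5, "T2": 0.9}), self._mk({"T2": 0.3, "T3": 0.6})],
            drug_id="X",
        )
        assert {(m.target_id, m.combined_score) for m in merged} == {
            ("T1", 0.5),
            ("T2", 0.9),
            ("T3", 0.6),
        }
        assert all(m.drug_id == "X" for m in merged)

    def test_sources_unioned(self):
        a = [DrugTargetInteraction("c1", "T", 0.5, frozenset({"stitch"}))]
        b = [DrugTargetInteraction("c2", "T", 0.3, frozenset({"batman"}))]
        (m,) = merge_composition_targets([a, b], drug_id="X")
        assert m.contributing_sources == {"stitch", "batman"}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            merge_composition_targets([])

    def test_threshold_applied_after_merge(self):
        # per-composition scores straddle the threshold: the merged max must
        # decide retention, not the individual compositions
        comps = [self._mk({"T1": 0.35, "T2": 0.45}), self._mk({"T1": 0.42})]
        merged = merge_composition_targets(comps, drug_id="X")
        kept = {i.target_id for i in filter_interactions(merged, 0.4)}
        assert kept == {"T1", "T2"}


class TestFilterInteractions:
    def test_strict_boundary(self):
        its = [
            DrugTargetInteraction("d", "T1", 0.72),
            DrugTargetInteraction("d", "T2", 0.40),
            DrugTargetInteraction("d", "T3", 0.41),
        ]
        assert {i.target_id for i in filter_interactions(its, 0.4)} == {"T1", "T3"}

    def test_zero_threshold_keeps_positive(self):
        its = [DrugTargetInteraction("d", f"T{i}", s) for i, s in enumerate([0.1, 0.9])]
        assert filter_interactions(its, 0.0) == its

    def test_empty_input(self):
        assert filter_interactions([], 0.4) == []

    def test_order_independent(self):
        its = [DrugTargetInteraction("d", f"T{i}", s)
               for i, s in enumerate([0.9, 0.2, 0.5])]
        fwd = {i.target_id for i in filter_interactions(its, 0.4)}
        rev = {i.target_id for i in filter_interactions(its[::-1], 0.4)}
        assert fwd == rev == {"T0", "T2"}


class TestClassConsensusTargets:
    def test_min_support_two(self):
        result = class_consensus_targets(
            {"d1": {"A", "B"}, "d2": {"B", "C"}, "d3": {"C"}}, min_support=2
        )
        assert result == {"B", "C"}

    def test_support_one_is_union(self):
        result = class_consensus_targets({"d1": {"A"}, "d2": {"B"}}, min_support=1)
        assert result == {"A", "B"}

    def test_unreachable_support_empty(self):
        assert class_consensus_targets({"d1": {"A"}}, min_support=2) == set()

    def test_invalid_support(self):
        with pytest.raises(ValueError):
            class_consensus_targets({"d1": {"A"}}, min_support=0)


class TestBuildNetwork:
    def test_hand_counted_edges(self):
        its = [
            DrugTargetInteraction("d1", "A", 0.9),
            DrugTargetInteraction("d1", "B", 0.8),
            DrugTargetInteraction("d2", "B", 0.7),
            DrugTargetInteraction("d2", "C", 0.3),  # filtered out
        ]
        sets = [
            GeneSet("P1", "one", frozenset({"A", "B"})),
            GeneSet("P2", "two", frozenset({"B", "C", "Z"})),
        ]
        net = build_network(its, sets, 0.4)
        assert net.dt_edges == {("d1", "A"), ("d1", "B"), ("d2", "B")}
        # C lost its interaction and Z never had one: excluded from tp edges
        assert net.tp_edges == {("A", "P1"), ("B", "P1"), ("B", "P2")}

    def test_untargeted_pathway_kept_with_zero_incidence(self, toy_network):
        assert "P_EMPTY" in toy_network.pathway_ids
        assert toy_network.pathway_members("P_EMPTY") == set()

    def test_degenerate_threshold_rejected(self):
        its = [DrugTargetInteraction("d", "T", 0.9)]
        with pytest.raises(ValueError, match="no drug-target interactions"):
            build_network(its, [GeneSet("P", "p", frozenset({"T"}))], 1.0)

    def test_full_tp_mode_keeps_non_target_genes(self):
        its = [DrugTargetInteraction("d", "A", 0.9)]
        sets = [GeneSet("P", "p", frozenset({"A", "Z"}))]
        net = build_network(its, sets, 0.4, restrict_tp=False)
        assert ("Z", "P") in net.tp_edges

    def test_random_toys_match_brute_force(self, rng):
        for _ in range(25):
            n_drugs = rng.integers(1, 5)
            n_targets = rng.integers(1, 8)
            its = [
                DrugTargetInteraction(f"d{i}", f"T{j}", float(rng.uniform(0, 1)))
                for i in range(n_drugs)
                for j in range(n_targets)
                if rng.random() < 0.5
            ]
            sets = [
                GeneSet(
                    f"P{k}",
                    f"p{k}",
                    frozenset(
                        {f"T{j}" for j in range(n_targets) if rng.random() < 0.5}
                        or {"T0"}
                    ),
                )
                for k in range(int(rng.integers(1, 4)))
            ]
            kept = [i for i in its if i.combined_score > 0.4]
            if not kept:
                with pytest.raises(ValueError):
                    build_network(its, sets, 0.4)
                continue
            net = build_network(its, sets, 0.4)
            expect_dt = {(i.drug_id, i.target_id) for i in kept}
            targets = {t for _, t in expect_dt}
            expect_tp = {
                (g, gs.pathway_id) for gs in sets for g in gs.genes if g in targets
            }
            assert net.dt_edges == expect_dt
            assert net.tp_edges == expect_tp


class TestRestrictPathways:
    @pytest.fixture
    def net(self):
        its = [DrugTargetInteraction("d", "A", 0.9)]
        sets = [
            GeneSet("P1", "inflammatory response", frozenset({"A"})),
            GeneSet("P2", "immune response", frozenset({"A"})),
        ]
        return build_network(its, sets, 0.4)

    def test_keyword_substring(self, net):
        sub = restrict_pathways(net, "INFLAMM")
        assert sub.pathway_ids == ["P1"]
        assert sub.dt_edges == net.dt_edges
        assert sub.tp_edges == {("A", "P1")}

    def test_full_id_list_is_identity(self, net):
        sub = restrict_pathways(net, ["P1", "P2"])
        assert sub.pathway_ids == net.pathway_ids
        assert sub.tp_edges == net.tp_edges

    def test_empty_selection_rejected(self, net):
        with pytest.raises(ValueError):
            restrict_pathways(net, [])
        with pytest.raises(ValueError):
            restrict_pathways(net, "")

    def test_no_match_rejected(self, net):
        with pytest.raises(ValueError, match="matches no pathway"):
            restrict_pathways(net, "metabolic")
        with pytest.raises(ValueError, match="unknown pathway"):
            restrict_pathways(net, ["P99"])


class TestInvariantsOnTypes:
    def test_evidence_probability_validated(self):
        with pytest.raises(ValueError):
            SourceEvidence("d", "T", "stitch", 1.5)

    def test_gene_set_nonempty(self):
        with pytest.raises(ValueError):
            GeneSet("P", "p", frozenset())

    def test_network_endpoint_invariant(self):
        from pathfin.hin import HeterogeneousNetwork

        with pytest.raises(ValueError, match="endpoint"):
            HeterogeneousNetwork(
                drugs=frozenset({"d"}),
                targets=frozenset({"T"}),
                pathways=(),
                dt_edges=frozenset({("other", "T")}),
                tp_edges=frozenset(),
                cs_threshold=0.4,
            )

    def test_combined_score_at_least_max_source(self, rng):
        for _ in range(50):
            probs = {f"s{i}": float(rng.uniform(0, 1)) for i in range(rng.integers(1, 5))}
            cs = combine_confidence(probs)
            assert cs >= max(probs.values()) - 1e-12
            assert cs <= 1.0

    def test_nan_score_rejected(self):
        with pytest.raises(ValueError):
            DrugTargetInteraction("d", "T", math.nan)
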