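import numpy as np
import pytest

from pathfin.hin import DrugTargetInteraction, GeneSet, build_network


@pytest.fixture
def toy_network():
    """2-drug toy: x targets {T1, T2}, y targets {T3}, one pathway with all
    three plus a pathway with no drug targets."""
    interactions = [
        DrugTargetInteraction("x", "T1", 0.9),
        DrugTargetInteraction("x", "T2", 0.8),
        DrugTargetInteraction("y", "T3", 0.7),
    ]
    gene_sets = [
        GeneSet("P1", "all three", frozenset({"T1", "T2", "T3"})),
        GeneSet("P_EMPTY", "untargeted", frozenset({"ZZZ1", "ZZZ2"})),
    ]
    return build_network(interactions, gene_sets, cs_threshold=0.4)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
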