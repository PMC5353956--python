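import numpy as np
import pytest

from netsort import DirectedNetwork, Edge, TopologyView
from netsort.synthetic import PlantedSpec, gen_planted_bowtie


def view_from_arcs(*arcs: tuple[str, str]) -> TopologyView:
    nodes = {x for arc in arcs for x in arc}
    return TopologyView(nodes=frozenset(nodes), arcs=frozenset(arcs))


def random_view(n_nodes: int, n_arcs: int, seed: int) -> TopologyView:
    """Uniform random simple digraph used across oracle tests."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    idx = rng.choice(len(pairs), size=min(n_arcs, len(pairs)), replace=False)
    arcs = frozenset(pairs[i] for i in idx)
    return TopologyView(nodes=frozenset(nodes), arcs=arcs)


@pytest.fixture
def chain_view() -> TopologyView:
    return view_from_arcs(("a", "b"), ("b", "c"))


@pytest.fixture
def toy_bowtie() -> tuple[DirectedNetwork, "object"]:
    """The documented (2,3,2,1,0) planted toy with no random extras."""
    return gen_planted_bowtie(PlantedSpec(), seed=0)


@pytest.fixture
def small_network() -> DirectedNetwork:
    """Hand-built signed network with enzymes and substrates."""
    edges = [
        Edge("K1", "K2", "P"),
        Edge("K2", "K1", "P"),
        Edge("K2", "S1", "P"),
        Edge("P1", "K1", "D"),
        Edge("K2", "S2", "P"),
    ]
    roles = {"K1": "kinase", "K2": "kinase", "P1": "phosphatase",
             "S1": "other", "S2": "other"}
    return DirectedNetwork.build(edges, roles=roles)
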