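"""Vertex sorting of a directed network into a bow-tie hierarchy.

The sort condenses strongly connected components, runs iterative leaf
removal on the resulting DAG and on its transpose, and reports a top-first
level interval per node.  Layers (top / core / bottom / peripheral) are
assigned from the largest SCC and its reachability sets; the global
reaching centrality (GRC) quantifies how hierarchical the network is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import networkx as nx
import numpy as np

from .errors import ValidationError
from .graph import (
    Condensation,
    EnzymeSubgraph,
    TopologyView,
    condensation_view,
    enzyme_subgraph,
    reach_sets,
    scc,
    topology,
)
from .network import DirectedNetwork

logger = logging.getLogger(__name__)

LAYERS = ("top", "core", "bottom", "peripheral")


@dataclass(frozen=True)
class LevelSpan:
    """Per-node level intervals from vertex sorting.

    ``b`` and ``t`` are the bottom-up leaf-removal iteration indices on the
    condensation DAG and its transpose; the reported interval is top-first
    (level 1 = apex): ``level_min = t``, ``level_max = D - b + 1``.
    """

    b: Mapping[str, int]
    t: Mapping[str, int]
    level_min: Mapping[str, int]
    level_max: Mapping[str, int]
    D: int

    def nodes(self) -> frozenset[str]:
        return frozenset(self.b)


@dataclass(frozen=True)
class LayerPartition:
    """Disjoint enzyme layers plus the substrates group.

    ``substrates`` holds non-enzyme nodes and isolated enzymes; it is empty
    when the partition was computed from a bare topology.
    """

    top: frozenset[str]
    core: frozenset[str]
    bottom: frozenset[str]
    peripheral: frozenset[str]
    substrates: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        layers = [self.top, self.core, self.bottom, self.peripheral]
        total = sum(len(s) for s in layers)
        if total != len(self.top | self.core | self.bottom | self.peripheral):
            raise ValidationError("layers must be pairwise disjoint")

    def layer_of(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for name in LAYERS:
            for n in getattr(self, name):
                out[n] = name
        for n in self.substrates:
            out[n] = "substrate"
        return out

    @property
    def sorted_nodes(self) -> frozenset[str]:
        return self.top | self.core | self.bottom | self.peripheral


@dataclass(frozen=True)
class GrcResult:
    """Local reaching centralities and the global reaching centrality."""

    local: Mapping[str, float]
    grc: float
    n: int


def leaf_removal(view: TopologyView) -> dict[str, int]:
    """Iteration index at which each node of an acyclic topology is removed.

    Iteration 1 removes all zero-out-degree nodes; each later iteration
    removes nodes whose out-neighbours have all been removed.
    """
    g = view.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        raise ValidationError("leaf removal requires an acyclic topology")
    out: dict[str, int] = {}
    # longest-path recursion: index = 1 + max(index of out-neighbours)
    for n in reversed(list(nx.topological_sort(g))):
        succ = list(g.successors(n))
        out[n] = 1 + max((out[s] for s in succ), default=0)
    return out


def vertex_sort(view: TopologyView) -> LevelSpan:
    """Sort *view* into level intervals via condensation + leaf removal."""
    if not view.nodes:
        raise ValidationError("cannot sort an empty network")
    if view.self_loops_included and any(u == v for u, v in view.arcs):
        view = topology(view, drop_self_loops=True)
    cond = scc(view)
    dag = condensation_view(cond)
    b_super = leaf_removal(dag)
    t_super = leaf_removal(dag.transpose())
    D = max(b_super.values())
    b = {n: b_super[cond.node_to_supernode[n]] for n in view.nodes}
    t = {n: t_super[cond.node_to_supernode[n]] for n in view.nodes}
    level_min = {n: t[n] for n in view.nodes}
    level_max = {n: D - b[n] + 1 for n in view.nodes}
    for n in view.nodes:
        if not 1 <= level_min[n] <= level_max[n] <= D:
            raise AssertionError(f"invalid span for {n}: {level_min[n]}..{level_max[n]}")
    return LevelSpan(b=b, t=t, level_min=level_min, level_max=level_max, D=D)


def _internal_arc_counts(view: TopologyView, cond: Condensation) -> dict[str, int]:
    counts = {label: 0 for label in cond.members}
    for u, v in view.arcs:
        lu, lv = cond.node_to_supernode[u], cond.node_to_supernode[v]
        if lu == lv:
            counts[lu] += 1
    return counts


def classify_layers(
    view: TopologyView, mode: Literal["path", "direct"] = "path"
) -> LayerPartition:
    """Assign each node of *view* to top / core / bottom / peripheral.

    The core is the largest SCC (ties by internal arc count, then smallest
    member id).  In ``path`` mode top/bottom are the ancestors/descendants
    of the core by directed paths; in ``direct`` mode only one-arc
    neighbours count.
    """
    if mode not in ("path", "direct"):
        raise ValidationError(f"unknown mode {mode!r}")
    if not view.nodes:
        raise ValidationError("cannot classify an empty topology")
    cond = scc(view)
    core_label = cond.largest(_internal_arc_counts(view, cond))
    core = cond.members[core_label]
    if len(core) == 1:
        warnings.warn(
            "largest SCC has a single node: degenerate bow tie", stacklevel=2
        )
    if mode == "path":
        top, bottom = reach_sets(view, core)
    else:
        top = frozenset(u for u, v in view.arcs if v in core and u not in core)
        bottom = frozenset(v for u, v in view.arcs if u in core and v not in core)
        overlap = top & bottom
        if overlap:  # direct-mode neighbour on both sides: place upstream
            bottom -= overlap
    peripheral = view.nodes - core - top - bottom
    return LayerPartition(
        top=frozenset(top),
        core=frozenset(core),
        bottom=frozenset(bottom),
        peripheral=frozenset(peripheral),
    )


@dataclass(frozen=True)
class SortResult:
    """Full sorting pipeline output for a signed network."""

    subgraph: EnzymeSubgraph
    spans: LevelSpan
    partition: LayerPartition


def sort_network(
    network: DirectedNetwork, mode: Literal["path", "direct"] = "path"
) -> SortResult:
    """Sort the enzyme subgraph of *network* and attach the substrates layer.

    Substrates = non-enzyme nodes plus enzymes isolated in the enzyme
    subgraph.
    """
    sub = enzyme_subgraph(network)
    if not sub.view.nodes:
        raise ValidationError("enzyme subgraph is empty; nothing to sort")
    spans = vertex_sort(sub.view)
    part = classify_layers(sub.view, mode=mode)
    substrates = (network.nodes - network.enzymes) | sub.isolated_enzymes
    return SortResult(
        subgraph=sub,
        spans=spans,
        partition=LayerPartition(
            top=part.top,
            core=part.core,
            bottom=part.bottom,
            peripheral=part.peripheral,
            substrates=frozenset(substrates),
        ),
    )


def grc(view: TopologyView) -> GrcResult:
    """Global reaching centrality of a topology.

    Local reaching centrality of a node is the fraction of the other N-1
    nodes it can reach; GRC is the average gap to the maximum, normalized
    by N-1.
    """
    n = view.n_nodes
    if n < 2:
        raise ValidationError("GRC needs at least 2 nodes")
    # descendant counts via SCC condensation + bitset closure over the DAG
    cond = scc(view)
    labels = sorted(cond.members)
    index = {label: i for i, label in enumerate(labels)}
    sizes = np.array([len(cond.members[lab]) for lab in labels], dtype=np.int64)
    s = len(labels)
    succ: list[set[int]] = [set() for _ in range(s)]
    for u, v in cond.dag_arcs:
        succ[index[u]].add(index[v])
    dag = nx.DiGraph()
    dag.add_nodes_from(range(s))
    dag.add_edges_from((index[u], index[v]) for u, v in cond.dag_arcs)
    reach = np.zeros((s, s), dtype=bool)
    for i in reversed(list(nx.topological_sort(dag))):
        for j in succ[i]:
            reach[i] |= reach[j]
            reach[i, j] = True
    desc_size = reach @ sizes  # nodes in strictly-downstream supernodes
    local: dict[str, float] = {}
    for node in sorted(view.nodes):
        i = index[cond.node_to_supernode[node]]
        local[node] = (int(desc_size[i]) + int(sizes[i]) - 1) / (n - 1)
    c_max = max(local.values())
    value = sum(c_max - c for c in local.values()) / (n - 1)
    return GrcResult(local=local, grc=value, n=n)


def grc_of_network(network: DirectedNetwork) -> GrcResult:
    """GRC of the full network (collapsed arcs, self-loops dropped)."""
    return grc(topology(network, drop_self_loops=True))


def layer_regulation_counts(
    network: DirectedNetwork, partition: LayerPartition
) -> dict[str, int]:
    """Distinct proteins targeted by each layer's enzymes in the full network."""
    counts: dict[str, int] = {}
    for name in LAYERS:
        members = getattr(partition, name)
        targets = {e.target for e in network.edges if e.source in members}
        counts[name] = len(targets)
    return counts
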