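"""Core directed-graph machinery: topology views, SCC condensation, reachability.

All functions iterate in sorted-identifier order so results are bit-for-bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import ValidationError
from .network import DirectedNetwork

Arc = tuple[str, str]


@dataclass(frozen=True)
class TopologyView:
    """Unsigned topology: unique (source, target) arcs over a node set.

    ``types`` maps each arc to the sorted tuple of sign codes that produced
    it (kept for reporting only; P/D multi-edges collapse to one arc).
    """

    nodes: frozenset[str]
    arcs: frozenset[Arc]
    self_loops_included: bool = False
    types: Mapping[Arc, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, v in self.arcs:
            if u not in self.nodes or v not in self.nodes:
                raise ValidationError(f"arc endpoint outside node set: {(u, v)}")
            if not self.self_loops_included and u == v:
                raise ValidationError(f"self-loop {u!r} present but not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.arcs))
        return g

    def with_arcs(self, arcs: Iterable[Arc]) -> "TopologyView":
        """Same nodes, different arcs (used by randomization schemes)."""
        return TopologyView(
            nodes=self.nodes,
            arcs=frozenset(arcs),
            self_loops_included=self.self_loops_included,
        )

    def transpose(self) -> "TopologyView":
        return TopologyView(
            nodes=self.nodes,
            arcs=frozenset((v, u) for u, v in self.arcs),
            self_loops_included=self.self_loops_included,
        )

    def in_degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for _, v in self.arcs:
            deg[v] += 1
        return deg

    def out_degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for u, _ in self.arcs:
            deg[u] += 1
        return deg


@dataclass(frozen=True)
class Condensation:
    """SCC partition plus the acyclic super-node graph.

    Super-node labels are the lexicographically smallest member identifier.
    """

    members: Mapping[str, frozenset[str]]
    node_to_supernode: Mapping[str, str]
    dag_arcs: frozenset[Arc]

    @property
    def supernodes(self) -> frozenset[str]:
        return frozenset(self.members)

    def largest(
        self, arc_counts: Mapping[str, int] | None = None
    ) -> str:
        """Label of the largest SCC; ties by internal-arc count, then id."""
        def key(label: str) -> tuple[int, int, str]:
            internal = -(arc_counts or {}).get(label, 0)
            return (-len(self.members[label]), internal, label)

        return min(self.members, key=key)


def topology(
    network: DirectedNetwork | TopologyView,
    drop_self_loops: bool = True,
) -> TopologyView:
    """Collapse signed multi-edges to unique arcs; optionally drop self-loops.

    P and D edges between the same ordered pair always collapse to a single
    arc; the signs are retained in ``TopologyView.types``.
    """
    if isinstance(network, TopologyView):
        arcs = {(u, v) for u, v in network.arcs if not (drop_self_loops and u == v)}
        return TopologyView(
            nodes=network.nodes,
            arcs=frozenset(arcs),
            self_loops_included=not drop_self_loops,
            types=dict(network.types),
        )
    type_map: dict[Arc, set[str]] = {}
    for e in network.edges:
        if drop_self_loops and e.source == e.target:
            continue
        type_map.setdefault((e.source, e.target), set()).add(e.itype)
    return TopologyView(
        nodes=network.nodes,
        arcs=frozenset(type_map),
        self_loops_included=not drop_self_loops,
        types={arc: tuple(sorted(ts)) for arc, ts in type_map.items()},
    )


def scc(view: TopologyView) -> Condensation:
    """Condense *view* into its strongly connected components."""
    g = view.to_networkx()
    members: dict[str, frozenset[str]] = {}
    node_to_supernode: dict[str, str] = {}
    for comp in nx.strongly_connected_components(g):
        label = min(comp)
        members[label] = frozenset(comp)
        for n in comp:
            node_to_supernode[n] = label
    dag_arcs = {
        (node_to_supernode[u], node_to_supernode[v])
        for u, v in view.arcs
        if node_to_supernode[u] != node_to_supernode[v]
    }
    return Condensation(
        members=members,
        node_to_supernode=node_to_supernode,
        dag_arcs=frozenset(dag_arcs),
    )


def condensation_view(cond: Condensation) -> TopologyView:
    return TopologyView(nodes=cond.supernodes, arcs=cond.dag_arcs)


def reach_sets(
    view: TopologyView, node_set: Iterable[str]
) -> tuple[frozenset[str], frozenset[str]]:
    """(ancestors, descendants) of *node_set* by directed paths, excluding it."""
    s = frozenset(node_set)
    if not s:
        raise ValidationError("node set must be non-empty")
    missing = s - view.nodes
    if missing:
        raise ValidationError(f"nodes not in topology: {sorted(missing)}")
    g = view.to_networkx()
    ancestors: set[str] = set()
    descendants: set[str] = set()
    for n in sorted(s):
        ancestors |= nx.ancestors(g, n)
        descendants |= nx.descendants(g, n)
    return frozenset(ancestors - s), frozenset(descendants - s)


@dataclass(frozen=True)
class EnzymeSubgraph:
    """Enzyme-induced topology plus the enzymes it leaves unconnected."""

    view: TopologyView
    isolated_enzymes: frozenset[str]


def enzyme_subgraph(
    network: DirectedNetwork, drop_self_loops: bool = True
) -> EnzymeSubgraph:
    """Induce the kinase/phosphatase subgraph.

    Enzymes with no remaining arc (after optional self-loop removal) are
    excluded from the view and reported as isolated.
    """
    enzymes = network.enzymes
    full = topology(network, drop_self_loops=drop_self_loops)
    arcs = frozenset(
        (u, v) for u, v in full.arcs if u in enzymes and v in enzymes
    )
    connected = {u for arc in arcs for u in arc}
    return EnzymeSubgraph(
        view=TopologyView(
            nodes=frozenset(connected),
            arcs=arcs,
            self_loops_included=not drop_self_loops,
        ),
        isolated_enzymes=frozenset(enzymes - connected),
    )
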