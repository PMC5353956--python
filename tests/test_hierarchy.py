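import numpy as np
import pytest

from netsort import (
    DirectedNetwork,
    Edge,
    TopologyView,
    classify_layers,
    grc,
    layer_regulation_counts,
    leaf_removal,
    sort_network,
    vertex_sort,
)
from netsort.errors import ValidationError
from netsort.synthetic import PlantedSpec, gen_planted_bowtie

from .conftest import random_view, view_from_arcs
from .oracles import brute_grc


class TestLeafRemoval:
    def test_chain(self, chain_view):
        assert leaf_removal(chain_view) == {"c": 1, "b": 2, "a": 3}

    def test_edgeless_graph_all_level_one(self):
        view = TopologyView(nodes=frozenset("abcd"), arcs=frozenset())
        assert set(leaf_removal(view).values()) == {1}

    def test_out_star(self):
        view = view_from_arcs(("hub", "x"), ("hub", "y"), ("hub", "z"))
        idx = leaf_removal(view)
        assert idx["hub"] == 2 and {idx["x"], idx["y"], idx["z"]} == {1}

    def test_cyclic_input_rejected(self):
        with pytest.raises(ValidationError, match="acyclic"):
            leaf_removal(view_from_arcs(("a", "b"), ("b", "a")))

    @pytest.mark.parametrize("seed", range(5))
    def test_max_index_is_longest_path_plus_one(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(12)]
        arcs = frozenset(
            (nodes[i], nodes[j])
            for i in range(12)
            for j in range(i + 1, 12)
            if rng.random() < 0.2
        )
        view = TopologyView(nodes=frozenset(nodes), arcs=arcs)
        idx = leaf_removal(view)
        assert max(idx.values()) == nx.dag_longest_path_length(view.to_networkx()) + 1


class TestVertexSort:
    def test_chain_spans(self, chain_view):
        spans = vertex_sort(chain_view)
        assert spans.D == 3
        assert (spans.level_min["a"], spans.level_max["a"]) == (1, 1)
        assert (spans.level_min["b"], spans.level_max["b"]) == (2, 2)
        assert (spans.level_min["c"], spans.level_max["c"]) == (3, 3)

    def test_branching_span(self):
        spans = vertex_sort(view_from_arcs(("a", "b"), ("a", "c"), ("c", "d")))
        assert spans.D == 3
        assert (spans.level_min["a"], spans.level_max["a"]) == (1, 1)
        assert (spans.level_min["c"], spans.level_max["c"]) == (2, 2)
        assert (spans.level_min["d"], spans.level_max["d"]) == (3, 3)
        assert (spans.level_min["b"], spans.level_max["b"]) == (2, 3)

    def test_scc_members_share_span(self):
        view = view_from_arcs(
            ("t", "c1"), ("c1", "c2"), ("c2", "c3"), ("c3", "c1"), ("c3", "b")
        )
        spans = vertex_sort(view)
        for n in ("c1", "c2", "c3"):
            assert spans.level_min[n] == spans.level_min["c1"]
            assert spans.level_max[n] == spans.level_max["c1"]

    @pytest.mark.parametrize("seed", range(10))
    def test_span_invariants(self, seed):
        view = random_view(20, 45, seed)
        spans = vertex_sort(view)
        for n in view.nodes:
            assert 1 <= spans.level_min[n] <= spans.level_max[n] <= spans.D
            assert spans.b[n] + spans.t[n] <= spans.D + 1

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            vertex_sort(TopologyView(nodes=frozenset(), arcs=frozenset()))


class TestClassifyLayers:
    def test_planted_toy(self):
        view = view_from_arcs(
            ("T1", "C1"), ("T2", "C2"),
            ("C1", "C2"), ("C2", "C3"), ("C3", "C1"),
            ("C2", "B1"), ("C3", "B2"), ("X1", "B1"),
        )
        part = classify_layers(view)
        assert part.top == frozenset({"T1", "T2"})
        assert part.core == frozenset({"C1", "C2", "C3"})
        assert part.bottom == frozenset({"B1", "B2"})
        assert part.peripheral == frozenset({"X1"})

    def test_pure_dag_degenerate_warning(self, chain_view):
        with pytest.warns(UserWarning, match="degenerate"):
            part = classify_layers(chain_view)
        assert len(part.core) == 1

    def test_direct_mode_uses_one_arc_neighbours(self):
        view = view_from_arcs(
            ("t2", "t1"), ("t1", "c1"), ("c1", "c2"), ("c2", "c1"),
            ("c2", "b1"), ("b1", "b2"),
        )
        path_part = classify_layers(view, mode="path")
        direct_part = classify_layers(view, mode="direct")
        assert path_part.top == frozenset({"t1", "t2"})
        assert direct_part.top == frozenset({"t1"})
        assert path_part.bottom == frozenset({"b1", "b2"})
        assert direct_part.bottom == frozenset({"b1"})


class TestGrc:
    def test_out_star_is_one(self):
        view = view_from_arcs(*((("hub", f"x{i}")) for i in range(6)))
        assert grc(view).grc == pytest.approx(1.0)

    def test_cycle_is_zero(self):
        view = view_from_arcs(("a", "b"), ("b", "c"), ("c", "a"))
        assert grc(view).grc == pytest.approx(0.0)

    def test_chain_three_quarters(self, chain_view):
        res = grc(chain_view)
        assert res.local == {"a": 1.0, "b": 0.5, "c": 0.0}
        assert res.grc == pytest.approx(0.75)

    def test_too_small_errors(self):
        with pytest.raises(ValidationError):
            grc(TopologyView(nodes=frozenset({"a"}), arcs=frozenset()))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        nodes = [f"n{i}" for i in range(n)]
        arcs = frozenset(
            (u, v) for u in nodes for v in nodes if u != v and rng.random() < 0.35
        )
        view = TopologyView(nodes=frozenset(nodes), arcs=arcs)
        assert grc(view).grc == pytest.approx(brute_grc(nodes, arcs))

    def test_relabel_invariance(self):
        view = random_view(12, 30, 3)
        mapping = {n: f"z{n}" for n in view.nodes}
        relabeled = TopologyView(
            nodes=frozenset(mapping.values()),
            arcs=frozenset((mapping[u], mapping[v]) for u, v in view.arcs),
        )
        assert grc(view).grc == pytest.approx(grc(relabeled).grc)

    def test_arc_from_max_node_cannot_increase_grc(self):
        view = view_from_arcs(("a", "b"), ("b", "c"), ("a", "d"))
        res = grc(view)
        top = max(res.local, key=res.local.get)
        for other in sorted(view.nodes - {top}):
            if (top, other) in view.arcs:
                continue
            grown = TopologyView(
                nodes=view.nodes, arcs=view.arcs | {(top, other)}
            )
            assert grc(grown).grc <= res.grc + 1e-12


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", range(100))
    def test_path_mode_recovers_planted_partition(self, seed):
        rng = np.random.default_rng(seed)
        spec = PlantedSpec(
            n_top=int(rng.integers(1, 6)),
            n_core=int(rng.integers(2, 6)),
            n_bottom=int(rng.integers(1, 6)),
            n_peripheral=int(rng.integers(0, 4)),
            n_substrates=int(rng.integers(0, 5)),
            p_top_core=0.3, p_core_core=0.3, p_core_bottom=0.3,
            p_top_bottom=0.2, p_enzyme_substrate=0.2,
        )
        net, truth = gen_planted_bowtie(spec, seed=seed)
        part = sort_network(net).partition
        assert part.top == truth.top
        assert part.core == truth.core
        assert part.bottom == truth.bottom
        assert part.peripheral == truth.peripheral
        assert part.substrates == truth.substrates


class TestLayerRegulationCounts:
    def test_core_counts_distinct_targets(self):
        net = DirectedNetwork.build(
            [Edge("C1", "S1", "P"), Edge("C1", "S2", "P"), Edge("C1", "S2", "D")],
            roles={"C1": "kinase"},
        )
        part = sort_network_core_only(net)
        counts = layer_regulation_counts(net, part)
        assert counts["core"] == 2

    def test_enzyme_target_counts_as_regulated(self, toy_bowtie):
        net, truth = toy_bowtie
        counts = layer_regulation_counts(net, truth)
        # core cycle: C1->C2, C2->C3, C3->C1 plus C2->B1, C3->B2
        assert counts["core"] == 5
        assert counts["top"] == 2  # T1->C1, T2->C2
        assert counts["peripheral"] == 1  # X1->B1


def sort_network_core_only(net):
    """Partition placing the lone enzyme in the core (degenerate by design)."""
    from netsort.hierarchy import LayerPartition

    return LayerPartition(
        top=frozenset(), core=frozenset({"C1"}), bottom=frozenset(),
        peripheral=frozenset(), substrates=frozenset({"S1", "S2"}),
    )
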