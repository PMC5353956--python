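"""Synthetic network and property generators.

Planted bow-ties with a known ground-truth partition, scale-free directed
networks, and layer-structured Gaussian property tables make the whole
toolkit testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import RngLike, as_rng
from .errors import ValidationError
from .hierarchy import LayerPartition
from .network import DirectedNetwork, Edge


@dataclass(frozen=True)
class PlantedSpec:
    """Block sizes and extra-arc probabilities for a planted bow tie.

    The deterministic skeleton (with all probabilities at 0) wires
    ``T_i -> C_i``, the core Hamiltonian cycle ``C_1 -> ... -> C_k -> C_1``,
    ``C_{(j mod k)+1} -> B_j`` and ``X_j -> B_{...}``; probabilities add
    seeded extra arcs inside and between blocks.
    """

    n_top: int = 2
    n_core: int = 3
    n_bottom: int = 2
    n_peripheral: int = 1
    n_substrates: int = 0
    p_top_core: float = 0.0
    p_core_core: float = 0.0
    p_core_bottom: float = 0.0
    p_top_bottom: float = 0.0
    p_enzyme_substrate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_top", "n_core", "n_bottom", "n_peripheral", "n_substrates"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_core < 1:
            raise ValidationError("planted core needs at least one node")
        for name in ("p_top_core", "p_core_core", "p_core_bottom",
                     "p_top_bottom", "p_enzyme_substrate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be a probability")
        if self.n_peripheral > 0 and self.n_bottom == 0 and self.n_top == 0:
            raise ValidationError(
                "peripheral nodes need a top or bottom block to attach to"
            )


def _names(prefix: str, n: int) -> list[str]:
    width = max(len(str(n)), 1)
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def gen_planted_bowtie(
    spec: PlantedSpec, seed: RngLike = None
) -> tuple[DirectedNetwork, LayerPartition]:
    """Generate a bow-tie network together with its ground-truth partition.

    The core sits on a directed Hamiltonian cycle (hence strongly
    connected); every top node sends at least one arc into the core and
    every bottom node receives at least one arc from it, so path-mode layer
    classification recovers the planted partition exactly.
    """
    rng = as_rng(seed)
    top = _names("T", spec.n_top)
    core = _names("C", spec.n_core)
    bottom = _names("B", spec.n_bottom)
    peri = _names("X", spec.n_peripheral)
    subs = _names("S", spec.n_substrates)
    enzymes = top + core + bottom + peri

    roles = {n: ("phosphatase" if i % 4 == 3 else "kinase")
             for i, n in enumerate(sorted(enzymes))}
    roles.update({s: "other" for s in subs})

    def etype(source: str) -> str:
        return "D" if roles[source] == "phosphatase" else "P"

    arcs: set[tuple[str, str]] = set()
    k = spec.n_core
    for i in range(k):  # Hamiltonian core cycle
        if k > 1:
            arcs.add((core[i], core[(i + 1) % k]))
    for i, t in enumerate(top):
        arcs.add((t, core[i % k]))
    for j, b in enumerate(bottom):
        arcs.add((core[(j + 1) % k], b))
    for j, x in enumerate(peri):
        if spec.n_bottom:
            arcs.add((x, bottom[j % spec.n_bottom]))
        else:
            arcs.add((top[j % spec.n_top], x))

    def add_random(sources: list[str], targets: list[str], p: float) -> None:
        if p <= 0 or not sources or not targets:
            return
        for u in sources:
            for v in targets:
                if u != v and rng.random() < p:
                    arcs.add((u, v))

    add_random(top, core, spec.p_top_core)
    add_random(core, core, spec.p_core_core)
    add_random(core, bottom, spec.p_core_bottom)
    add_random(top, bottom, spec.p_top_bottom)
    for j, s in enumerate(subs):  # every substrate regulated at least once
        arcs.add((sorted(enzymes)[j % len(enzymes)], s))
    add_random(enzymes, subs, spec.p_enzyme_substrate)

    edges = [Edge(u, v, etype(u)) for u, v in sorted(arcs)]
    network = DirectedNetwork.build(edges, roles=roles)
    truth = LayerPartition(
        top=frozenset(top),
        core=frozenset(core),
        bottom=frozenset(bottom),
        peripheral=frozenset(peri),
        substrates=frozenset(subs),
    )
    return network, truth


def gen_powerlaw_network(
    n_nodes: int, gamma: float, seed: RngLike = None, max_retries: int = 100
) -> DirectedNetwork:
    """Directed network whose out-degrees follow a discrete power law.

    Out-degrees are exact inverse-CDF draws from P(K) ∝ K^-gamma (K >= 1,
    capped at n-1); targets are uniform without duplicates or self-loops.
    """
    from .metrics import sample_discrete_powerlaw

    if gamma <= 1:
        raise ValidationError("gamma must exceed 1")
    if n_nodes < 10:
        raise ValidationError("need at least 10 nodes")
    rng = as_rng(seed)
    nodes = _names("n", n_nodes)
    degrees = sample_discrete_powerlaw(n_nodes, gamma, rng=rng)
    degrees = np.minimum(degrees, n_nodes - 1)
    edges: list[Edge] = []
    for i, u in enumerate(nodes):
        d = int(degrees[i])
        others = [v for v in nodes if v != u]
        targets = rng.choice(len(others), size=d, replace=False)
        edges.extend(Edge(u, others[t], "P") for t in targets)
    roles = {n: "kinase" for n in nodes}
    return DirectedNetwork.build(edges, roles=roles)


def gen_layer_properties(
    partition: LayerPartition,
    layer_params: dict[str, tuple[float, float]],
    missing_fraction: float = 0.0,
    seed: RngLike = None,
    name: str = "prop",
) -> pd.Series:
    """Gaussian per-layer property draws with a masked-missing fraction."""
    if not 0.0 <= missing_fraction <= 1.0:
        raise ValidationError("missing_fraction must be in [0, 1]")
    rng = as_rng(seed)
    values: dict[str, float] = {}
    for layer, (mean, sd) in sorted(layer_params.items()):
        if sd < 0:
            raise ValidationError(f"negative SD for layer {layer!r}")
        for node in sorted(getattr(partition, layer)):
            values[node] = float(rng.normal(mean, sd))
    series = pd.Series(values, dtype=float, name=name).sort_index()
    if missing_fraction > 0 and len(series):
        n_missing = int(round(missing_fraction * len(series)))
        drop = rng.choice(len(series), size=n_missing, replace=False)
        series.iloc[drop] = np.nan
    return series
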