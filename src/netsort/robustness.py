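"""Layer stability under edge noise: perturb, re-sort, compare layers.

Subsampled networks delete random signed edges; noisy networks add random
enzyme-sourced edges.  Stability is the per-layer Jaccard similarity between
the original and perturbed partitions; overlap significance uses the
hypergeometric test over the enzymes sorted in both networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from ._rng import RngLike, as_rng, replicate_rng
from .errors import ValidationError
from .hierarchy import LayerPartition, sort_network
from .network import DirectedNetwork, Edge
from .stats import hypergeom_test

Mode = Literal["add", "delete"]
DEFAULT_KS = (40, 80, 120, 160, 200)
_LAYERS = ("top", "core", "bottom")


@dataclass(frozen=True)
class LayerComparison:
    jaccard: Mapping[str, float]
    overlap_p: Mapping[str, float]
    universe_size: int


@dataclass(frozen=True)
class RobustnessResult:
    """Mean Jaccard and per-replicate overlap p-values per mode x k x layer."""

    mean_jaccard: Mapping[str, Mapping[int, Mapping[str, float]]]
    overlap_p: Mapping[str, Mapping[int, Mapping[str, tuple[float, ...]]]]
    ks: tuple[int, ...]
    reps: int
    seed: int


def perturb_edges(
    network: DirectedNetwork,
    mode: Mode,
    k: int,
    seed: RngLike = None,
    sources: Literal["enzymes", "all"] = "enzymes",
) -> DirectedNetwork:
    """Delete k random signed edges, or add k new enzyme-sourced edges.

    Added edges never duplicate an existing (source, target) arc and never
    form a self-loop; a kinase source phosphorylates (type P), a phosphatase
    dephosphorylates (type D).
    """
    if mode not in ("add", "delete"):
        raise ValidationError(f"unknown mode {mode!r}")
    if k < 0:
        raise ValidationError("k must be non-negative")
    rng = as_rng(seed)
    edges = network.sorted_edges()
    if mode == "delete":
        if k > len(edges):
            raise ValidationError(f"cannot delete {k} of {len(edges)} edges")
        keep = set(range(len(edges))) - set(
            rng.choice(len(edges), size=k, replace=False).tolist()
        )
        return network.replace_edges(edges[i] for i in sorted(keep))

    pool = sorted(network.enzymes) if sources == "enzymes" else sorted(network.nodes)
    if not pool:
        raise ValidationError("no eligible source nodes")
    nodes = sorted(network.nodes)
    existing = {(e.source, e.target) for e in edges}
    capacity = sum(
        len(nodes) - 1 - sum(1 for t in nodes if (s, t) in existing) for s in pool
    )
    if k > capacity:
        raise ValidationError(f"cannot add {k} edges: only {capacity} slots free")
    new: list[Edge] = []
    while len(new) < k:
        s = pool[int(rng.integers(0, len(pool)))]
        t = nodes[int(rng.integers(0, len(nodes)))]
        if s == t or (s, t) in existing:
            continue
        itype = "D" if network.roles[s] == "phosphatase" else "P"
        new.append(Edge(s, t, itype))
        existing.add((s, t))
    return network.replace_edges(edges + new)


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    union = set(a) | set(b)
    if not union:
        return 0.0
    return len(set(a) & set(b)) / len(union)


def layer_stability(
    original: LayerPartition,
    perturbed: LayerPartition,
    layers: Sequence[str] = _LAYERS,
) -> LayerComparison:
    """Per-layer Jaccard similarity and hypergeometric overlap p-value.

    The overlap universe is the set of sorted enzymes (all four layers)
    common to both partitions.
    """
    universe = original.sorted_nodes & perturbed.sorted_nodes
    n_univ = len(universe)
    jac: dict[str, float] = {}
    pvals: dict[str, float] = {}
    for name in layers:
        orig = getattr(original, name)
        pert = getattr(perturbed, name)
        if not orig or not pert:
            warnings.warn(f"empty {name} layer in a partition", stacklevel=2)
            jac[name] = 0.0
            pvals[name] = 1.0
            continue
        jac[name] = jaccard(orig, pert)
        ou, pu = orig & universe, pert & universe
        k = len(ou & pu)
        if n_univ == 0 or not ou or not pu:
            pvals[name] = 1.0
        else:
            pvals[name] = hypergeom_test(
                k=k, K=len(ou), n=len(pu), N=n_univ, direction="enrichment"
            ).p
    return LayerComparison(jaccard=jac, overlap_p=pvals, universe_size=n_univ)


def robustness_suite(
    network: DirectedNetwork,
    ks: Sequence[int] = DEFAULT_KS,
    reps: int = 100,
    seed: int = 0,
    modes: Sequence[Mode] = ("add", "delete"),
    layers: Sequence[str] = _LAYERS,
) -> RobustnessResult:
    """Perturb / re-sort / compare, for every mode x perturbation size."""
    base = sort_network(network).partition
    mean_jac: dict[str, dict[int, dict[str, float]]] = {}
    pvals: dict[str, dict[int, dict[str, tuple[float, ...]]]] = {}
    stream = 0
    for mode in modes:
        mean_jac[mode] = {}
        pvals[mode] = {}
        for k in ks:
            acc = {name: 0.0 for name in layers}
            ps: dict[str, list[float]] = {name: [] for name in layers}
            for r in range(reps):
                rng = replicate_rng(seed, stream)
                stream += 1
                pert = perturb_edges(network, mode, k, seed=rng)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    part = sort_network(pert).partition
                    comp = layer_stability(base, part, layers=layers)
                for name in layers:
                    acc[name] += comp.jaccard[name]
                    ps[name].append(comp.overlap_p[name])
            mean_jac[mode][int(k)] = {n: acc[n] / reps for n in layers}
            pvals[mode][int(k)] = {n: tuple(ps[n]) for n in layers}
    return RobustnessResult(
        mean_jaccard=mean_jac, overlap_p=pvals, ks=tuple(int(k) for k in ks),
        reps=reps, seed=seed,
    )
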