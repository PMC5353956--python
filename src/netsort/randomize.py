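"""Degree-constrained network randomization schemes and empirical p-values.

Five schemes rewire an observed topology under decreasingly strict degree
constraints — DPR (both degree sequences exact), SDPR (both to within one),
IDPR (in-degrees exact), ODPR (out-degrees exact), DNPR (only node and arc
counts) — plus uniform Erdős–Rényi G(n, m) graphs.  All generators are
deterministic given a seed, contain no self-loops and no duplicate arcs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import networkx as nx
import numpy as np

from ._rng import RngLike, as_rng, replicate_rng
from .errors import RandomizationError, ValidationError
from .graph import Arc, TopologyView

SCHEMES = ("dpr", "sdpr", "idpr", "odpr", "dnpr", "er")
Tail = Literal["ge", "le"]

_MAX_TRIES_FACTOR = 200


def _swap_once(
    arcs: list[Arc], arcset: set[Arc], rng: np.random.Generator
) -> bool:
    """Attempt one end-exchange of two random arcs; True if accepted."""
    m = len(arcs)
    i, j = rng.integers(0, m, size=2)
    if i == j:
        return False
    a, b = arcs[i]
    c, d = arcs[j]
    new1, new2 = (a, d), (c, b)
    if a == d or c == b or new1 == new2:
        return False
    if new1 in arcset or new2 in arcset:
        return False
    arcset.remove(arcs[i])
    arcset.remove(arcs[j])
    arcs[i], arcs[j] = new1, new2
    arcset.add(new1)
    arcset.add(new2)
    return True


def dpr(
    view: TopologyView, n_swaps: int = 10000, seed: RngLike = None
) -> TopologyView:
    """Degree-preserving randomization by repeated end exchange of arc pairs.

    Performs ``n_swaps`` accepted swaps; a proposal creating a self-loop or
    duplicate arc is rejected and re-drawn.
    """
    if view.n_arcs < 2:
        raise ValidationError("need at least 2 arcs to swap")
    rng = as_rng(seed)
    arcs = sorted(view.arcs)
    arcset = set(arcs)
    accepted = 0
    attempts = 0
    limit = _MAX_TRIES_FACTOR * max(n_swaps, 1)
    while accepted < n_swaps:
        if attempts >= limit:
            raise RandomizationError(
                f"only {accepted}/{n_swaps} swaps accepted after {attempts} "
                "attempts: network too small or rigid"
            )
        attempts += 1
        if _swap_once(arcs, arcset, rng):
            accepted += 1
    return view.with_arcs(arcs)


def _repair_collisions(
    arcs: list[Arc], rng: np.random.Generator, max_tries_per: int = 100
) -> list[Arc]:
    """Resolve duplicate arcs and self-loops by switching them with random arcs.

    Each offending arc is end-exchanged with a randomly selected arc, as in
    the degree-preserving swap, until the multiset is a simple arc set.
    """

    def bad_indices() -> list[int]:
        seen: dict[Arc, int] = {}
        bad = []
        for idx, arc in enumerate(arcs):
            if arc[0] == arc[1] or arc in seen:
                bad.append(idx)
            else:
                seen[arc] = idx
        return bad

    bad = bad_indices()
    budget = max_tries_per * max(len(bad), 1) * 10
    tries = 0
    while bad:
        if tries >= budget:
            raise RandomizationError(
                f"could not resolve {len(bad)} duplicate/self-loop arc(s)"
            )
        tries += 1
        i = bad[int(rng.integers(0, len(bad)))]
        j = int(rng.integers(0, len(arcs)))
        if i == j:
            continue
        a, b = arcs[i]
        c, d = arcs[j]
        new1, new2 = (a, d), (c, b)
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue
        trial = arcs.copy()
        trial[i], trial[j] = new1, new2

        def n_bad(lst: list[Arc]) -> int:
            seen: set[Arc] = set()
            k = 0
            for arc in lst:
                if arc[0] == arc[1] or arc in seen:
                    k += 1
                else:
                    seen.add(arc)
            return k

        # accept only if strictly fewer offending positions
        if n_bad(trial) < len(bad):
            arcs[:] = trial
            bad = bad_indices()
    return arcs


def _degree_draw(
    deg: dict[str, int], rng: np.random.Generator
) -> dict[str, int]:
    """Per-node target degree drawn uniformly from {d, d+1, max(d-1, 0)}."""
    out = {}
    for n in sorted(deg):
        shift = int(rng.integers(0, 3))  # 0: same, 1: +1, 2: -1
        d = deg[n] + (1 if shift == 1 else -1 if shift == 2 else 0)
        out[n] = max(d, 0)
    return out


def _match_stubs(
    in_target: dict[str, int],
    out_target: dict[str, int],
    rng: np.random.Generator,
    max_restarts: int = 50,
) -> list[Arc]:
    """Pair in/out stubs with probability ∝ (remaining stubs)²; no collisions.

    Dead ends trigger a full restart of the pairing phase.
    """
    nodes = sorted(in_target)
    for _ in range(max_restarts):
        in_rem = np.array([in_target[n] for n in nodes], dtype=float)
        out_rem = np.array([out_target[n] for n in nodes], dtype=float)
        arcs: set[Arc] = set()
        ok = True
        while out_rem.sum() > 0:
            placed = False
            for _try in range(200):
                pw = out_rem**2
                u = int(rng.choice(len(nodes), p=pw / pw.sum()))
                qw = in_rem**2
                v = int(rng.choice(len(nodes), p=qw / qw.sum()))
                if u == v or (nodes[u], nodes[v]) in arcs:
                    continue
                arcs.add((nodes[u], nodes[v]))
                out_rem[u] -= 1
                in_rem[v] -= 1
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return sorted(arcs)
    raise RandomizationError("stub matching dead-ended repeatedly")


def sdpr(
    view: TopologyView, n_swaps: int = 10000, seed: RngLike = None,
    max_draws: int = 500,
) -> TopologyView:
    """Similar-degree-preserving randomization via the stub-matching algorithm.

    Target in/out degree sequences are the observed ones perturbed by at
    most one per node; the network is rebuilt by squared-weight stub
    pairing, then degree-preserving switched.
    """
    if view.n_arcs < 2:
        raise ValidationError("need at least 2 arcs")
    rng = as_rng(seed)
    in_deg, out_deg = view.in_degrees(), view.out_degrees()
    for _ in range(max_draws):
        in_t = _degree_draw(in_deg, rng)
        out_t = _degree_draw(out_deg, rng)
        if sum(in_t.values()) == sum(out_t.values()) and sum(in_t.values()) >= 2:
            break
    else:
        raise RandomizationError("could not draw a balanced degree sequence")
    arcs = _match_stubs(in_t, out_t, rng)
    randomized = view.with_arcs(arcs)
    return dpr(randomized, n_swaps=n_swaps, seed=rng)


def column_randomize(
    view: TopologyView,
    column: Literal["from", "to"],
    seed: RngLike = None,
    enzymes: Iterable[str] | None = None,
    source_pool: Literal["enzymes", "all"] = "enzymes",
    target_pool: Literal["all", "enzymes"] = "all",
    n_swaps: int = 10000,
) -> TopologyView:
    """IDPR (column="from") or ODPR (column="to") randomization.

    The chosen column is resampled with replacement — sources from the
    enzyme list, targets from all nodes by default — and the collisions the
    resampling creates are resolved by switching; a final degree-preserving
    switch decorrelates the replicates.  The untouched column's per-node
    degree sequence is preserved exactly.
    """
    if column not in ("from", "to"):
        raise ValidationError(f"column must be 'from' or 'to', got {column!r}")
    rng = as_rng(seed)
    arcs = sorted(view.arcs)
    if not arcs:
        raise ValidationError("empty topology")
    if column == "from":
        pool = sorted(enzymes) if (enzymes is not None and source_pool == "enzymes") \
            else sorted({u for u, _ in arcs} if source_pool == "enzymes" else view.nodes)
        if not pool:
            raise ValidationError("no enzymes available to resample sources")
        new_sources = rng.choice(pool, size=len(arcs), replace=True)
        arcs = [(str(s), t) for s, (_, t) in zip(new_sources, arcs)]
    else:
        pool = sorted(view.nodes) if target_pool == "all" else sorted(
            enzymes if enzymes is not None else {u for u, _ in arcs}
        )
        if not pool:
            raise ValidationError("empty target pool")
        new_targets = rng.choice(pool, size=len(arcs), replace=True)
        arcs = [(s, str(t)) for (s, _), t in zip(arcs, new_targets)]
    arcs = _repair_collisions(arcs, rng)
    return dpr(view.with_arcs(arcs), n_swaps=n_swaps, seed=rng)


def dnpr(
    view: TopologyView,
    seed: RngLike = None,
    enzymes: Iterable[str] | None = None,
    sources_enzymes_only: bool = False,
) -> TopologyView:
    """Degree-non-preserving randomization: same nodes and arc count only."""
    n, m = view.n_nodes, view.n_arcs
    if n < 2:
        raise ValidationError("need at least 2 nodes")
    if m > n * (n - 1):
        raise ValidationError("arc count exceeds simple-digraph capacity")
    rng = as_rng(seed)
    nodes = sorted(view.nodes)
    src_pool = sorted(enzymes) if (sources_enzymes_only and enzymes) else nodes
    arcs: set[Arc] = set()
    limit = _MAX_TRIES_FACTOR * max(m, 1) * 10
    tries = 0
    while len(arcs) < m:
        if tries >= limit:
            raise RandomizationError("could not place all arcs without collisions")
        tries += 1
        u = src_pool[int(rng.integers(0, len(src_pool)))]
        v = nodes[int(rng.integers(0, n))]
        if u != v:
            arcs.add((u, v))
    return view.with_arcs(arcs)


def erdos_renyi(
    n_nodes: int, n_arcs: int, seed: RngLike = None,
    node_names: Sequence[str] | None = None,
) -> TopologyView:
    """Uniform simple directed G(n, m) graph without self-loops."""
    if n_arcs > n_nodes * (n_nodes - 1):
        raise ValidationError("infeasible arc count")
    rng = as_rng(seed)
    g = nx.gnm_random_graph(
        n_nodes, n_arcs, seed=int(rng.integers(0, 2**32)), directed=True
    )
    if node_names is None:
        width = len(str(max(n_nodes - 1, 0)))
        node_names = [f"v{idx:0{width}d}" for idx in range(n_nodes)]
    elif len(node_names) != n_nodes:
        raise ValidationError("node_names length must equal n_nodes")
    names = list(node_names)
    return TopologyView(
        nodes=frozenset(names),
        arcs=frozenset((names[u], names[v]) for u, v in g.edges()),
    )


def randomize(
    view: TopologyView,
    scheme: str,
    seed: RngLike = None,
    enzymes: Iterable[str] | None = None,
    n_swaps: int = 10000,
    **kwargs,
) -> TopologyView:
    """Dispatch to one randomization scheme by code (case-insensitive)."""
    code = scheme.lower()
    if code == "dpr":
        return dpr(view, n_swaps=n_swaps, seed=seed)
    if code == "sdpr":
        return sdpr(view, n_swaps=n_swaps, seed=seed)
    if code == "idpr":
        return column_randomize(view, "from", seed=seed, enzymes=enzymes,
                                n_swaps=n_swaps, **kwargs)
    if code == "odpr":
        return column_randomize(view, "to", seed=seed, enzymes=enzymes,
                                n_swaps=n_swaps, **kwargs)
    if code == "dnpr":
        return dnpr(view, seed=seed, enzymes=enzymes, **kwargs)
    if code == "er":
        return erdos_renyi(view.n_nodes, view.n_arcs, seed=seed,
                           node_names=sorted(view.nodes))
    raise ValidationError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


def replicates(
    view: TopologyView,
    scheme: str,
    n_reps: int,
    seed: int,
    enzymes: Iterable[str] | None = None,
    n_swaps: int = 10000,
    **kwargs,
):
    """Yield (index, randomized topology); replicate i depends only on (seed, i)."""
    for i in range(n_reps):
        yield i, randomize(
            view, scheme, seed=replicate_rng(seed, i), enzymes=enzymes,
            n_swaps=n_swaps, **kwargs,
        )


@dataclass(frozen=True)
class EmpiricalPvalue:
    """Observed statistic against a randomized-null ensemble."""

    observed: float
    p: float
    tail: str
    scheme: str
    n_reps: int
    seed: int
    null_mean: float
    null_sd: float
    null_quantiles: dict = field(default_factory=dict)
    null_values: tuple = ()


def empirical_pvalue(
    view: TopologyView,
    statistic: Callable[[TopologyView], float],
    scheme: str,
    n_reps: int,
    seed: int,
    tail: Tail = "ge",
    enzymes: Iterable[str] | None = None,
    n_swaps: int = 10000,
    keep_null: bool = False,
    **kwargs,
) -> EmpiricalPvalue:
    """Fraction of scheme replicates whose statistic is as extreme as observed."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if tail not in ("ge", "le"):
        raise ValidationError("tail must be 'ge' or 'le'")
    observed = float(statistic(view))
    null = np.empty(n_reps)
    for i, rep in replicates(view, scheme, n_reps, seed, enzymes=enzymes,
                             n_swaps=n_swaps, **kwargs):
        null[i] = statistic(rep)
    hits = (null >= observed) if tail == "ge" else (null <= observed)
    q = np.quantile(null, [0.025, 0.5, 0.975])
    return EmpiricalPvalue(
        observed=observed,
        p=float(hits.mean()),
        tail=tail,
        scheme=scheme.lower(),
        n_reps=n_reps,
        seed=seed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_reps > 1 else 0.0,
        null_quantiles={"q2.5": float(q[0]), "q50": float(q[1]), "q97.5": float(q[2])},
        null_values=tuple(null.tolist()) if keep_null else (),
    )
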