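"""Independent brute-force oracles used to validate the package's algorithms.

Everything here is deliberately naive (adjacency dictionaries, exhaustive
enumeration) and shares no code with netsort's implementations.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations, permutations


def reachable_from(nodes, arcs, start) -> set:
    """Nodes reachable from start by >= 1 arc (BFS on a raw arc list)."""
    succ = {}
    for u, v in arcs:
        succ.setdefault(u, set()).add(v)
    seen: set = set()
    queue = deque(succ.get(start, ()))
    while queue:
        x = queue.popleft()
        if x in seen:
            continue
        seen.add(x)
        queue.extend(succ.get(x, ()))
    return seen


def brute_scc(nodes, arcs) -> set[frozenset]:
    """SCCs by pairwise mutual reachability."""
    nodes = list(nodes)
    reach = {n: reachable_from(nodes, arcs, n) for n in nodes}
    comps = []
    assigned = set()
    for n in nodes:
        if n in assigned:
            continue
        comp = {n} | {m for m in nodes if m in reach[n] and n in reach[m]}
        comps.append(frozenset(comp))
        assigned |= comp
    return set(comps)


def closure_matrix(nodes, arcs) -> dict:
    """Floyd-Warshall transitive closure: closure[u][v] True iff path u->v."""
    nodes = list(nodes)
    c = {u: {v: False for v in nodes} for u in nodes}
    for u, v in arcs:
        c[u][v] = True
    for k in nodes:
        for i in nodes:
            if c[i][k]:
                for j in nodes:
                    if c[k][j]:
                        c[i][j] = True
    return c


def brute_grc(nodes, arcs) -> float:
    nodes = list(nodes)
    n = len(nodes)
    local = [len(reachable_from(nodes, arcs, v) - {v}) / (n - 1) for v in nodes]
    cmax = max(local)
    return sum(cmax - c for c in local) / (n - 1)


def brute_motifs(nodes, arcs) -> tuple[int, int, int]:
    """(ffl, fbl2, bifan) by exhaustive enumeration of triples/quadruples."""
    arcset = set(arcs)
    nodes = sorted(nodes)
    ffl = sum(
        1
        for a, b, c in permutations(nodes, 3)
        if (a, b) in arcset and (b, c) in arcset and (a, c) in arcset
    )
    fbl2 = sum(
        1 for a, b in combinations(nodes, 2) if (a, b) in arcset and (b, a) in arcset
    )
    bifan = 0
    for srcs in combinations(nodes, 2):
        for tgts in combinations(nodes, 2):
            if set(srcs) & set(tgts):
                continue
            a, b = srcs
            c, d = tgts
            if all(x in arcset for x in [(a, c), (a, d), (b, c), (b, d)]):
                bifan += 1
    return ffl, fbl2, bifan


def brute_betweenness(nodes, arcs) -> dict:
    """Raw betweenness by BFS shortest-path counting through every node."""
    succ = {n: set() for n in nodes}
    for u, v in arcs:
        succ[u].add(v)

    def shortest_paths(s, t):
        # enumerate all shortest s->t paths by BFS layering
        if s == t:
            return []
        dist = {s: 0}
        q = deque([s])
        while q:
            x = q.popleft()
            for y in succ[x]:
                if y not in dist:
                    dist[y] = dist[x] + 1
                    q.append(y)
        if t not in dist:
            return []
        paths = []

        def walk(node, acc):
            if node == t:
                paths.append(acc)
                return
            for y in succ[node]:
                if dist.get(y) == dist[node] + 1 and dist[y] <= dist[t]:
                    walk(y, acc + [y])

        walk(s, [s])
        return [p for p in paths if len(p) - 1 == dist[t]]

    bt = {n: 0.0 for n in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = shortest_paths(s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                frac = sum(1 for p in paths if v in p) / len(paths)
                bt[v] += frac
    return bt


def brute_hypergeom(k, K, n, N, direction) -> float:
    """Exact tail sum of the hypergeometric mass from binomial coefficients."""
    from math import comb

    total = comb(N, n)
    lo = max(0, n + K - N)
    hi = min(n, K)
    support = range(k, hi + 1) if direction == "enrichment" else range(lo, k + 1)
    return sum(comb(K, x) * comb(N - K, n - x) for x in support) / total


def exact_rt_pvalue(a, b, alternative="greater") -> float:
    """Exact permutation p for the difference of means over all splits."""
    pool = list(a) + list(b)
    la = len(a)
    obs = sum(a) / len(a) - sum(b) / len(b)
    count = 0
    total = 0
    eps = 1e-12
    for idx in combinations(range(len(pool)), la):
        sa = [pool[i] for i in idx]
        sb = [pool[i] for i in range(len(pool)) if i not in idx]
        diff = sum(sa) / la - sum(sb) / len(sb)
        total += 1
        if alternative == "greater" and diff >= obs - eps:
            count += 1
        elif alternative == "less" and diff <= obs + eps:
            count += 1
        elif alternative == "two_sided" and abs(diff) >= abs(obs) - eps:
            count += 1
    return count / total
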