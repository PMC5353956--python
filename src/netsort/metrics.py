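"""Centralities, hub/bottleneck selection, motif counts and power-law fits."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
from scipy import optimize, special

from ._rng import RngLike, as_rng
from .errors import FitError, ValidationError
from .graph import TopologyView


@dataclass(frozen=True)
class MotifCounts:
    """Feed-forward loops, 2-node feedback loops and bi-fans."""

    ffl: int
    fbl2: int
    bifan: int


@dataclass(frozen=True)
class PowerLawFit:
    gamma: float
    xmin: int
    gof_p: float
    n_tail: int
    ks: float


def betweenness(view: TopologyView) -> dict[str, float]:
    """Raw directed shortest-path betweenness (unnormalized pair-fraction sum)."""
    g = view.to_networkx()
    return dict(nx.betweenness_centrality(g, normalized=False))


def select_top_fraction(
    scores: Mapping[str, float], fraction: float = 0.2
) -> frozenset[str]:
    """The floor(fraction * n) highest-scoring ids; cut ties go to smaller id."""
    if not scores:
        raise ValidationError("empty score table")
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    k = int(np.floor(fraction * len(scores)))
    ranked = sorted(scores, key=lambda n: (-scores[n], n))
    return frozenset(ranked[:k])


def count_motifs(view: TopologyView) -> MotifCounts:
    """Exact counts of the three motif classes; self-loops must be absent."""
    if any(u == v for u, v in view.arcs):
        raise ValidationError("drop self-loops before motif counting")
    succ: dict[str, set[str]] = {n: set() for n in view.nodes}
    pred: dict[str, set[str]] = {n: set() for n in view.nodes}
    arcset = view.arcs
    for u, v in arcset:
        succ[u].add(v)
        pred[v].add(u)

    # FFL: ordered triples (A,B,C), A->B, B->C, A->C, all distinct.
    ffl = 0
    for a, b in arcset:
        ffl += sum(1 for c in succ[b] if c != a and (a, c) in arcset)

    fbl2 = sum(1 for u, v in arcset if u < v and (v, u) in arcset)

    # Bi-fan: unordered {A,B} x unordered {C,D}, 4 distinct nodes, all four
    # arcs present.  Count common-target pairs per source pair.
    bifan = 0
    nodes = sorted(view.nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            common = succ[a] & succ[b] - {a, b}
            m = len(common)
            if m >= 2:
                bifan += m * (m - 1) // 2
    return MotifCounts(ffl=ffl, fbl2=fbl2, bifan=bifan)


# -- discrete power-law fitting (MLE + KS xmin scan + bootstrap GOF) --------


def _mle_gamma(tail: np.ndarray, xmin: int) -> float:
    logsum = float(np.sum(np.log(tail)))
    n = len(tail)

    def nll(gamma: float) -> float:
        return n * np.log(special.zeta(gamma, xmin)) + gamma * logsum

    res = optimize.minimize_scalar(nll, bounds=(1.0001, 12.0), method="bounded")
    return float(res.x)


def _ks_distance(tail: np.ndarray, xmin: int, gamma: float) -> float:
    values, counts = np.unique(tail, return_counts=True)
    ecdf = np.cumsum(counts) / len(tail)
    z = special.zeta(gamma, xmin)
    cdf = 1.0 - special.zeta(gamma, values + 1) / z
    return float(np.max(np.abs(ecdf - cdf)))


def _fit_xmin(data: np.ndarray) -> tuple[float, int, float, int]:
    candidates = np.unique(data)[:-1] if len(np.unique(data)) > 1 else np.unique(data)
    best: tuple[float, int, float, int] | None = None
    for xmin in candidates:
        tail = data[data >= xmin]
        if len(tail) < 5 or len(np.unique(tail)) < 2:
            continue
        gamma = _mle_gamma(tail, int(xmin))
        ks = _ks_distance(tail, int(xmin), gamma)
        if best is None or ks < best[2]:
            best = (gamma, int(xmin), ks, len(tail))
    if best is None:
        raise FitError("no viable xmin: degree sequence too degenerate")
    return best


def sample_discrete_powerlaw(
    n: int, gamma: float, xmin: int = 1, rng: RngLike = None, support_max: int = 10**6
) -> np.ndarray:
    """Exact inverse-CDF samples from P(X=k) ∝ k^-gamma, k in [xmin, support_max]."""
    rng = as_rng(rng)
    k = np.arange(xmin, support_max + 1, dtype=float)
    pmf = k**-gamma
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    u = rng.random(n)
    return (np.searchsorted(cdf, u) + xmin).astype(np.int64)


def powerlaw_fit(
    degrees, n_bootstrap: int = 0, seed: RngLike = None
) -> PowerLawFit:
    """Clauset-style discrete power-law fit of a positive degree sequence.

    The exponent is the discrete maximum-likelihood estimate, the lower
    cut-off minimizes the tail Kolmogorov–Smirnov distance, and the
    goodness-of-fit probability (when ``n_bootstrap`` > 0) comes from the
    semi-parametric bootstrap: synthetic samples mix draws from the fitted
    tail with resamples of the observed body.
    """
    data = np.asarray(degrees, dtype=np.int64)
    if len(data) < 10:
        raise ValidationError("need at least 10 degree observations")
    if np.any(data < 1):
        raise ValidationError("degrees must be positive integers")
    if len(np.unique(data)) == 1:
        raise FitError("all degrees equal: power-law fit undefined")
    gamma, xmin, ks, n_tail = _fit_xmin(data)

    gof_p = float("nan")
    if n_bootstrap > 0:
        rng = as_rng(seed)
        body = data[data < xmin]
        p_tail = n_tail / len(data)
        exceed = 0
        for _ in range(n_bootstrap):
            from_tail = rng.random(len(data)) < p_tail
            n_t = int(from_tail.sum())
            parts = []
            if n_t:
                parts.append(
                    sample_discrete_powerlaw(n_t, gamma, xmin=xmin, rng=rng,
                                             support_max=10**5)
                )
            if len(data) - n_t:
                if len(body) == 0:
                    parts.append(
                        sample_discrete_powerlaw(len(data) - n_t, gamma,
                                                 xmin=xmin, rng=rng,
                                                 support_max=10**5)
                    )
                else:
                    parts.append(rng.choice(body, size=len(data) - n_t))
            synth = np.concatenate(parts)
            try:
                _, _, ks_s, _ = _fit_xmin(synth)
            except FitError:
                continue
            if ks_s >= ks:
                exceed += 1
        gof_p = exceed / n_bootstrap
    return PowerLawFit(gamma=gamma, xmin=xmin, gof_p=gof_p, n_tail=n_tail, ks=ks)
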