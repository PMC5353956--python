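"""Layer-comparison statistics.

* randomization (permutation) test for a difference of group means,
* hypergeometric enrichment / depletion of a node category,
* rank association between a property and node degree,
* random-network layer profiles (property means per layer across a
  randomized ensemble, with percentile confidence intervals).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import RngLike, as_rng, replicate_rng
from .errors import FitError, ValidationError
from .graph import TopologyView, topology
from .hierarchy import classify_layers
from .network import DirectedNetwork
from .randomize import randomize

Alternative = Literal["greater", "less", "two_sided", "auto"]
_EPS = 1e-12


@dataclass(frozen=True)
class RtResult:
    observed_diff: float
    p: float
    alternative: str
    n_resamples: int
    n_a: int
    n_b: int
    seed: int | None = None
    exact: bool = False


@dataclass(frozen=True)
class HtResult:
    k: int
    K: int
    n: int
    N: int
    direction: str
    p: float


@dataclass(frozen=True)
class LayerProfile:
    layers: tuple[str, ...]
    observed: Mapping[str, float]
    null_mean: Mapping[str, float]
    ci_low: Mapping[str, float]
    ci_high: Mapping[str, float]
    scheme: str
    n_reps: int
    seed: int


def _clean(values) -> np.ndarray:
    arr = np.asarray(pd.Series(list(values), dtype=float).dropna(), dtype=float)
    return arr


def randomization_test(
    values_a,
    values_b,
    n_resamples: int = 10000,
    alternative: Alternative = "auto",
    seed: RngLike = None,
    exact: bool = False,
) -> RtResult:
    """Permutation test for the difference of group means.

    Pools both groups, redraws groups of the original sizes without
    replacement and reports the fraction of resampled differences at least
    as extreme as observed.  ``alternative="auto"`` tests one-sided in the
    direction of the observed difference.  With ``exact=True`` all splits
    are enumerated (feasible for small pools) and ``n_resamples`` ignored.
    """
    a, b = _clean(values_a), _clean(values_b)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError(
            "a group is empty after missing-value removal "
            f"(sizes {len(a)} and {len(b)})"
        )
    observed = float(a.mean() - b.mean())
    if alternative == "auto":
        alternative = "greater" if observed >= 0 else "less"
    if alternative not in ("greater", "less", "two_sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    n, la = len(pooled), len(a)

    def extreme(diffs: np.ndarray) -> np.ndarray:
        if alternative == "greater":
            return diffs >= observed - _EPS
        if alternative == "less":
            return diffs <= observed + _EPS
        return np.abs(diffs) >= abs(observed) - _EPS

    if exact:
        total = math.comb(n, la)
        if total > 5_000_000:
            raise ValidationError(f"exact enumeration infeasible: {total} splits")
        tot_sum = pooled.sum()
        diffs = np.empty(total)
        for idx, comb in enumerate(combinations(range(n), la)):
            sa = pooled[list(comb)].sum()
            diffs[idx] = sa / la - (tot_sum - sa) / (n - la)
        return RtResult(
            observed_diff=observed,
            p=float(extreme(diffs).mean()),
            alternative=alternative,
            n_resamples=total,
            n_a=la,
            n_b=n - la,
            exact=True,
        )

    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    rng = as_rng(seed)
    # argsort of uniforms = random subsets of size la, vectorized
    order = np.argsort(rng.random((n_resamples, n)), axis=1)[:, :la]
    sa = pooled[order].sum(axis=1)
    diffs = sa / la - (pooled.sum() - sa) / (n - la)
    return RtResult(
        observed_diff=observed,
        p=float(extreme(diffs).mean()),
        alternative=alternative,
        n_resamples=n_resamples,
        n_a=la,
        n_b=n - la,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def hypergeom_test(
    k: int, K: int, n: int, N: int,
    direction: Literal["enrichment", "depletion"] = "enrichment",
) -> HtResult:
    """Exact hypergeometric tail probability for category overlap.

    ``k`` successes in a selection of ``n`` from a universe of ``N``
    containing ``K`` successes.  Enrichment: P(X >= k); depletion: P(X <= k).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid universe: K={K}, n={n}, N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValidationError(
            f"k={k} outside support [{max(0, n + K - N)}, {min(n, K)}]"
        )
    if direction not in ("enrichment", "depletion"):
        raise ValidationError(f"unknown direction {direction!r}")
    dist = sps.hypergeom(N, K, n)
    p = float(dist.sf(k - 1)) if direction == "enrichment" else float(dist.cdf(k))
    return HtResult(k=k, K=K, n=n, N=N, direction=direction, p=min(p, 1.0))


def degree_association(
    property_values, degree_values, n_permutations: int = 10000,
    seed: RngLike = None,
) -> tuple[float, float]:
    """Spearman rank correlation with a permutation p-value (two-sided)."""
    x = np.asarray(list(property_values), dtype=float)
    y = np.asarray(list(degree_values), dtype=float)
    if len(x) != len(y):
        raise ValidationError("paired observations required")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ValidationError("need at least 5 paired observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise FitError("constant input: rank correlation undefined")
    rho = float(sps.spearmanr(x, y).statistic)
    rng = as_rng(seed)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        perm[i] = float(np.mean(rx * rng.permutation(ry)))
    p = float(np.mean(np.abs(perm) >= abs(np.mean(rx * ry)) - _EPS))
    return rho, p


def _enzyme_layer_means(
    view: TopologyView,
    enzymes: frozenset[str],
    prop: pd.Series,
    layers: Sequence[str],
) -> dict[str, float]:
    """Sort the enzyme-induced part of *view* and average *prop* per layer."""
    arcs = frozenset((u, v) for u, v in view.arcs if u in enzymes and v in enzymes)
    connected = {x for arc in arcs for x in arc}
    if not connected:
        return {name: float("nan") for name in layers}
    sub = TopologyView(nodes=frozenset(connected), arcs=arcs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        part = classify_layers(sub)
    out = {}
    for name in layers:
        members = sorted(getattr(part, name))
        vals = prop.reindex(members).dropna()
        out[name] = float(vals.mean()) if len(vals) else float("nan")
    return out


def layer_profile(
    network: DirectedNetwork,
    prop: pd.Series | Mapping[str, float],
    scheme: str,
    n_reps: int = 1000,
    seed: int = 0,
    n_swaps: int = 10000,
    layers: Sequence[str] = ("top", "core", "bottom"),
    **scheme_kwargs,
) -> LayerProfile:
    """Mean of a node property per layer across a randomized ensemble.

    Each replicate randomizes the full network under *scheme*, re-sorts its
    enzyme subgraph, and averages *prop* within each layer; the profile is
    the across-replicate mean with a percentile 95% confidence interval,
    alongside the observed network's layer means.
    """
    if not isinstance(prop, pd.Series):
        prop = pd.Series(dict(prop), dtype=float)
    view = topology(network, drop_self_loops=True)
    enzymes = network.enzymes
    observed = _enzyme_layer_means(view, enzymes, prop, layers)
    null = {name: np.empty(n_reps) for name in layers}
    for i in range(n_reps):
        rep = randomize(view, scheme, seed=replicate_rng(seed, i),
                        enzymes=enzymes, n_swaps=n_swaps, **scheme_kwargs)
        means = _enzyme_layer_means(rep, enzymes, prop, layers)
        for name in layers:
            null[name][i] = means[name]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        null_mean = {k: float(np.nanmean(v)) for k, v in null.items()}
        ci_low = {k: float(np.nanpercentile(v, 2.5)) for k, v in null.items()}
        ci_high = {k: float(np.nanpercentile(v, 97.5)) for k, v in null.items()}
    return LayerProfile(
        layers=tuple(layers),
        observed=observed,
        null_mean=null_mean,
        ci_low=ci_low,
        ci_high=ci_high,
        scheme=scheme.lower(),
        n_reps=n_reps,
        seed=seed,
    )
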