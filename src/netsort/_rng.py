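"""Seed-derivation helpers: every replicate is reproducible from (seed, index)."""

from __future__ import annotations

import numpy as np

RngLike = int | np.random.Generator | None


def as_rng(seed: RngLike) -> np.random.Generator:
    """Coerce an int seed / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def replicate_rng(seed: int, index: int) -> np.random.Generator:
    """Independent stream for replicate *index* of a run with base *seed*."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(index))))
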