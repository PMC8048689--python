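"""Seed handling: one user-facing seed, deterministic derived streams."""

from __future__ import annotations

import numpy as np

__all__ = ["as_rng", "spawn_rngs"]


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed / SeedSequence / Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(base_seed, n: int) -> list[np.random.Generator]:
    """``n`` independent deterministic child generators from one base seed."""
    if isinstance(base_seed, np.random.SeedSequence):
        ss = base_seed
    else:
        ss = np.random.SeedSequence(base_seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]
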