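"""Seed handling: every stochastic entry point accepts an int seed, a
SeedSequence or a Generator; child streams are split with SeedSequence so
independent stages never share a stream."""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.SeedSequence | np.random.Generator | None"


def as_rng(seed=None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    """n independent child seed sequences derived from ``seed``."""
    if isinstance(seed, np.random.Generator):
        # derive children from the generator stream itself
        ints = seed.integers(0, 2 ** 31 - 1, size=n)
        return [np.random.SeedSequence(int(i)) for i in ints]
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    return list(seed.spawn(n))
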