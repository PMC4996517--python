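"""Seed plumbing: every stochastic operation accepts an int, None, a
SeedSequence or a Generator, and derives per-task child streams from it."""

from __future__ import annotations

import numpy as np


def seed_sequence(seed) -> np.random.SeedSequence:
    """Coerce any accepted seed spec into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        return seed.bit_generator.seed_seq.spawn(1)[0]
    return np.random.SeedSequence(seed)


def rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed_sequence(seed))
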