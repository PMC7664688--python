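"""Deterministic seed hierarchy.

One master seed governs a run; every stochastic stage derives its own
generator as ``rng(master, *keys)`` where the keys are small integers
(subject index, question index, fold index, stage tag).  Any subset of the
pipeline is therefore reproducible in isolation.
"""

from __future__ import annotations

import numpy as np

# stage tags keep per-stage streams disjoint even at equal numeric keys
STAGE = {
    "design": 1,
    "baseline": 2,
    "signal": 3,
    "artifact": 4,
    "selection": 5,
    "classifier": 6,
}


def rng(master: int, *keys: int) -> np.random.Generator:
    """Child generator for (master seed, integer key path)."""
    return np.random.default_rng(np.random.SeedSequence([int(master), *map(int, keys)]))


def child_seed(master: int, *keys: int) -> int:
    """A plain integer child seed (< 2**31), for APIs that want one."""
    ss = np.random.SeedSequence([int(master), *map(int, keys)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
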