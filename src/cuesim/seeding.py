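"""Deterministic counter-based RNG splitting.

One root seed governs a whole run; every simulated unit (cell, repetition,
observer, function) derives its own independent generator from the root
seed plus its integer coordinates.  Any unit is therefore reproducible in
isolation and results are invariant to execution order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng", "child_seed_sequence"]


def child_seed_sequence(root_seed: int, *key: int) -> np.random.SeedSequence:
    """Seed sequence for the unit addressed by integer coordinates ``key``."""
    return np.random.SeedSequence(entropy=(int(root_seed),) + tuple(int(k) for k in key))


def child_rng(root_seed: int, *key: int) -> np.random.Generator:
    """Independent generator for the unit addressed by ``key``."""
    return np.random.default_rng(child_seed_sequence(root_seed, *key))
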