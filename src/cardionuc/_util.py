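"""Small shared helpers: seeded RNGs and seed derivation."""
from __future__ import annotations

import hashlib

import numpy as np

MAX_SEED = 2**31 - 1


def derive_seed(base_seed: int, *tags) -> int:
    """Derive a reproducible child seed below 2**31 from a base seed and tags.

    Stages/cells derive independent streams from one global seed so each is
    reproducible in isolation.
    """
    key = ":".join([str(int(base_seed))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode()).hexdigest()
    return int(digest, 16) % MAX_SEED


def rng_from(seed: int, *tags) -> np.random.Generator:
    if tags:
        seed = derive_seed(seed, *tags)
    return np.random.default_rng(seed)
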