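"""Deterministic seed derivation.

One master seed; every stochastic sub-task (locus i, bootstrap b, replicate r)
derives its generator from ``(master, *tags)`` via numpy's SeedSequence, so
tasks are independent, order-insensitive, and byte-reproducible.
"""

from __future__ import annotations

import numpy as np


def spawn_rng(master: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(master),) + tuple(int(t) for t in tags)))


def derive_seed(master: int, *tags: int) -> int:
    """A 31-bit child seed, for manifests and APIs that take plain ints."""
    ss = np.random.SeedSequence((int(master),) + tuple(int(t) for t in tags))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
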