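"""Seed handling.

A single integer seed feeds :class:`numpy.random.SeedSequence`; sub-streams
for independent simulation stages are spawned from it so that changing the
number of draws in one stage never perturbs another.
"""

from __future__ import annotations

import numpy as np

# derived integer seeds are kept below 2**31 so they survive any int32 sink
_SEED_MOD = 2**31


def rng_from_seed(seed: int) -> np.random.Generator:
    """Deterministic generator for a single stage."""
    return np.random.default_rng(np.random.SeedSequence(seed))


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1, dtype=np.uint64)[0] % _SEED_MOD) for c in children]
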