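"""Seed-derivation helpers.

All stochastic stages draw from numpy Generators built here so that one
master seed deterministically fixes every stage and every subject.
"""
from __future__ import annotations

import numpy as np

_MOD = 2**31 - 1


def derive_seed(master: int, *keys) -> int:
    """Derive a child seed (< 2^31) from a master seed and hashable keys.

    Stable across processes: strings are folded byte-wise rather than via
    Python's randomized hash().
    """
    acc = int(master) % _MOD
    for key in keys:
        if isinstance(key, str):
            folded = 0
            for b in key.encode():
                folded = (folded * 131 + b) % _MOD
        else:
            folded = int(key) % _MOD
        acc = (acc * 1_000_003 + folded + 0x9E3779B9) % _MOD
    return acc


def rng_for(master: int, *keys) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *keys))
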