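"""Seed-handling helpers.

A single run seed drives every randomized step through named substreams:
the substream for a given test is derived by hashing the run seed together
with stable string tokens (e.g. the factor ids of a triplet).  Adding or
removing factors therefore never reshuffles the permutations of unrelated
tests, and identical (seed, tokens) always reproduce the same stream.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(seed: int, *tokens: str) -> int:
    """A stable 31-bit child seed from a run seed and string tokens."""
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(seed)).encode())
    for t in tokens:
        h.update(b"\x00" + str(t).encode())
    return int.from_bytes(h.digest(), "big") & 0x7FFFFFFF


def spawn_rng(seed=None, *tokens: str) -> np.random.Generator:
    """A Generator for (seed, tokens); passes through existing Generators."""
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        return np.random.default_rng()
    if tokens:
        return np.random.default_rng(derive_seed(int(seed), *tokens))
    return np.random.default_rng(int(seed))
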