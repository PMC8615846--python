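"""Deterministic, named random substreams.

Every stochastic operation in the package draws from a substream derived from a
master seed plus a tuple of string/int keys (e.g. ``("subject", 3, "transfer")``).
Adding subjects or stages therefore never perturbs the draws of existing ones,
and identical (seed, keys) always reproduce identical data.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "key_to_int"]


def key_to_int(key) -> int:
    """Map a str/int key to a stable 32-bit integer."""
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError("integer substream keys must be non-negative")
        return int(key) & 0xFFFFFFFF
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8")) & 0xFFFFFFFF
    raise TypeError(f"substream keys must be str or int, got {type(key).__name__}")


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``."""
    if master_seed is None:
        raise ValueError("a master seed is required (got None)")
    spawn_key = tuple(key_to_int(k) for k in keys)
    ss = np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF, spawn_key=spawn_key)
    return np.random.default_rng(ss)
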