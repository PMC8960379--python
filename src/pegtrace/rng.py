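"""Deterministic substream derivation.

Every stochastic routine in the package derives its generator from one
top-level seed plus a tuple of string/integer tags, so outputs are
byte-identical for a fixed seed regardless of call order.
"""

from __future__ import annotations

import zlib

import numpy as np


def _tag_to_int(tag) -> int:
    if isinstance(tag, str):
        # crc32 is stable across processes (unlike hash() on str)
        return zlib.crc32(tag.encode("utf-8"))
    return int(tag) & 0xFFFFFFFF


def substream(seed: int, *tags) -> np.random.Generator:
    """Return a Generator for the substream identified by ``tags``.

    Two calls with the same (seed, tags) yield independent copies of the
    same stream; different tags yield statistically independent streams.
    """
    key = tuple(_tag_to_int(t) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=key))
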