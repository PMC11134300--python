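"""Deterministic named RNG substreams.

All randomness in the package flows from one integer seed fanned out to
per-stage substreams, so changing one stage's stream leaves the others'
outputs unchanged.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The substream key is a CRC32 of the name, so it is stable across
    processes and Python versions (unlike ``hash``).
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,))
    return np.random.default_rng(ss)
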