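"""Deterministic seed fan-out.

A single master seed is expanded into named substreams so that every stage
(and every sample pair inside the null models) draws from an independent,
reproducible stream. Adding a stage or changing pair iteration order never
perturbs another stream's randomness.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream_seed(master_seed: int, *keys) -> np.random.SeedSequence:
    """Derive a SeedSequence from a master seed and a tuple of string/int keys."""
    entropy = [int(master_seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, (int, np.integer)):
            entropy.append(int(k) & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(k).encode("utf-8")))
    return np.random.SeedSequence(entropy)


def substream(master_seed: int, *keys) -> np.random.Generator:
    """A PCG64 generator on the named substream."""
    return np.random.default_rng(substream_seed(master_seed, *keys))
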