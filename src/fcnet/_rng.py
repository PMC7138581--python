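"""Deterministic per-stage random substreams.

All randomness in the pipeline flows from a single integer seed.  Each
stage (and each subject/level/index within a stage) derives its own
independent substream by hashing string keys into the seed material, so
adding or reordering stages never perturbs another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed", "seed_sequence"]


def _entropy(seed: int, keys: tuple) -> list[int]:
    ints = [int(seed) & 0xFFFFFFFF]
    for key in keys:
        ints.append(zlib.crc32(str(key).encode("utf-8")))
    return ints


def seed_sequence(seed: int, *keys) -> np.random.SeedSequence:
    """SeedSequence keyed by ``seed`` and a tuple of stage keys."""
    return np.random.SeedSequence(_entropy(seed, keys))


def substream(seed: int, *keys) -> np.random.Generator:
    """Independent Generator for stage ``keys`` under master ``seed``."""
    return np.random.default_rng(seed_sequence(seed, *keys))


def substream_seed(seed: int, *keys) -> int:
    """A 32-bit integer seed for external RNGs (numba kernels)."""
    return int(seed_sequence(seed, *keys).generate_state(1, np.uint32)[0])
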