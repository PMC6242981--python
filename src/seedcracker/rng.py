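"""Seed plumbing.

Every stochastic operation takes one integer seed and derives a private
child stream from ``(seed, operation-name)``, so adding or reordering calls
never perturbs the streams of unrelated operations.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _entropy(seed: int, name: str) -> tuple[int, int]:
    return (int(seed), zlib.crc32(name.encode("utf-8")))


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Generator for operation ``name`` under the global ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(_entropy(seed, name)))


def child_seed(seed: int, name: str) -> int:
    """Derived 31-bit integer seed (for RNGs that take a plain int)."""
    ss = np.random.SeedSequence(_entropy(seed, name))
    return int(ss.generate_state(1)[0] % (2**31))
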