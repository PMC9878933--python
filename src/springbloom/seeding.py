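"""Deterministic per-operation random streams.

A single integer seed drives the whole simulator.  Each stochastic
operation draws from its own stream, derived from the global seed and a
stable hash of the operation name, so that e.g. adding a second observation
channel never perturbs the draws of the first.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """A sub-seed below 2**31, stable across sessions (crc32, not hash())."""
    return (int(seed) ^ zlib.crc32(name.encode("utf-8"))) % (2**31)


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Generator for operation ``name`` under global ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), child_seed(seed, name)]))
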