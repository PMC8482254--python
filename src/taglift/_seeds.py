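"""Deterministic seed derivation.

Every source of randomness in the package is a numpy Generator seeded from a
(global seed, stream name) pair via SHA-256, so adding draws to one stage
never perturbs another, and the same (seed, name) pair yields the same stream
on every platform.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(seed: int, name: str) -> int:
    """Map (seed, name) to a stable integer in [0, 2**31)."""
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """A fresh Generator for the named stream."""
    return np.random.default_rng(derive_seed(seed, name))
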