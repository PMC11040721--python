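"""Seed fan-out and small shared helpers.

A single experiment seed is split into independent per-stage child seeds by
hashing ``"{seed}:{label}"`` with SHA-256 and reducing modulo 2**31.  The rule
is deterministic across platforms and lets any stage be regenerated in
isolation from the master seed and its stage label.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(master_seed: int, label: str) -> int:
    digest = hashlib.sha256(f"{int(master_seed)}:{label}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


def rng_for(master_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, label))
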