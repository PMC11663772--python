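"""Deterministic seed derivation.

A single master seed expands into independent child streams, one per
pipeline stage / replicate, so each stage is reproducible in isolation
and replicates can run in any order with order-invariant aggregation.
Path components are hashed with CRC32 so the scheme is stable across
platforms and Python processes (unlike ``hash()``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def _key(component) -> int:
    if isinstance(component, (int, np.integer)):
        return int(component) & 0xFFFFFFFF
    return zlib.crc32(str(component).encode("utf-8"))


def child_seed_sequence(master: int, *path) -> np.random.SeedSequence:
    """SeedSequence for the stage identified by ``path`` under ``master``."""
    return np.random.SeedSequence([int(master) & 0x7FFFFFFF] + [_key(p) for p in path])


def child_rng(master: int, *path) -> np.random.Generator:
    """Independent generator for the stage identified by ``path``."""
    return np.random.default_rng(child_seed_sequence(master, *path))
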