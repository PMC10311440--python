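"""Seed-hierarchy helpers.

A single master seed spawns named, independent substreams so that each
pipeline stage (covariates, exposures, outcomes, bootstrap, ...) can be
re-run in isolation and still reproduce exactly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for", "child_seeds"]


def rng_for(seed: int, *stage: str | int) -> np.random.Generator:
    """Return a Generator for a named stage under a master seed.

    The stage path is hashed into the entropy pool via SeedSequence's
    spawn_key mechanism, so distinct paths give independent streams.
    """
    # crc32 (not built-in hash, which is salted per process) keeps paths stable
    key = tuple(
        zlib.crc32(s.encode()) if isinstance(s, str) else int(s) for s in stage
    )
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


def child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible integer seeds (< 2**31) derived from a master seed."""
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]
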