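"""Seed-substream plumbing.

All randomness in the package flows from one root integer seed. Named
substreams let each stage (calls, sightings, relatedness, experiments...)
be regenerated independently without perturbing the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seeds"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The same (seed, name) pair always yields an identical stream; distinct
    names yield statistically independent streams.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def child_seeds(seed: int, name: str, n: int) -> np.ndarray:
    """Return ``n`` integer seeds (< 2**31) derived from a named substream."""
    rng = substream(seed, name)
    return rng.integers(0, 2**31 - 1, size=n)
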