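"""Named RNG substreams.

A single master seed drives every stochastic stage, but each stage pulls an
independent substream identified by a name, so stages (population generation,
roll draw, area draw, quarter assignment, ...) can be re-run or replaced
independently without perturbing the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _name_key(name: str) -> int:
    # stable across processes/platforms, unlike hash()
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``."""
    keys = tuple(_name_key(n) for n in names)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=keys))


def spawn_seed(seed: int, *names: str) -> int:
    """Derive a child integer seed (< 2**31) from a master seed and names."""
    return int(substream(seed, *names).integers(0, 2**31 - 1))
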