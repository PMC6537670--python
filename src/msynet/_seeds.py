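"""Derivation of independent, named random substreams from one root seed.

Every stochastic operation in the package draws from a stream obtained via
:func:`substream`, so that a single top-level integer seed makes whole
pipeline runs reproducible while keeping per-operation streams independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a generator for the substream identified by ``names``.

    The stream depends only on ``seed`` and the name path, never on the
    order in which other streams were consumed.
    """
    key = tuple(zlib.crc32(str(n).encode("utf-8")) for n in names)
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=key)
    return np.random.default_rng(ss)
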