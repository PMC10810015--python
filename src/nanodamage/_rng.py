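"""Seed plumbing: named, independent random substreams.

All randomness flows from one root seed.  Each module draws from its own
named substream (derived via ``numpy.random.SeedSequence`` with a stable
hash of the stream name), so adding draws in one module never perturbs
the sequence seen by another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int | None, name: str) -> np.random.Generator:
    """Generator for the named substream of ``seed``.

    ``seed=None`` gives fresh OS entropy (still namespaced).
    """
    key = zlib.crc32(name.encode())
    if seed is None:
        ss = np.random.SeedSequence(spawn_key=(key,))
    else:
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
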