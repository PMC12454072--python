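"""Deterministic seed plumbing.

Every source of randomness in the package derives from a single experiment
seed through named sub-streams, so any intermediate draw can be traced back
to (seed, *tags).
"""

from __future__ import annotations

import zlib

import numpy as np


def subseed(seed: int, *tags) -> int:
    """Derive a stable 31-bit sub-seed from a root seed and a tag path.

    Tags may be strings or integers; the mapping is independent of Python's
    per-process hash randomization.
    """
    h = zlib.crc32(str(int(seed)).encode())
    for tag in tags:
        h = zlib.crc32(str(tag).encode(), h)
    return h & 0x7FFFFFFF


def rng_for(seed: int, *tags) -> np.random.Generator:
    """A fresh Generator for the named sub-stream."""
    return np.random.default_rng(subseed(seed, *tags))
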