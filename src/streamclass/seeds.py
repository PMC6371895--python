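"""Named random substreams.

All randomness in the package flows from one integer seed.  Each consumer
derives an independent generator from (seed, name), so enabling or disabling
one pipeline layer never perturbs another layer's draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic generator for a named substream of ``seed``."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def subseed(seed: int, name: str) -> int:
    """A plain integer seed (< 2^31) for libraries that take one."""
    return int(substream(seed, name).integers(0, 2**31 - 1))
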