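"""Seeded random streams, one per operation.

Every stochastic operation draws from its own generator, seeded from the
pair (user seed, CRC32 of the operation name).  Adding a new generator to
the package therefore never perturbs the stream of an existing one, and a
single integer seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

from zlib import crc32

import numpy as np


def stream(seed: int, operation: str) -> np.random.Generator:
    """Return the dedicated generator for *operation* under *seed*."""
    if seed is None:
        raise ValueError("a seed is required; it is never defaulted silently")
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, crc32(operation.encode())])
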