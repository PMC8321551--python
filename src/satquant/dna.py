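"""Byte-level DNA helpers shared by the simulators and the toy mapper.

Sequences are handled as ``numpy.uint8`` arrays of ASCII codes so that
mutation, reverse complement, and Hamming scans stay vectorised.
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMP = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


def encode(seq: str) -> np.ndarray:
    """ASCII-encode a sequence string into a uint8 array."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def complement_array(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr]


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr][::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_array(encode(seq)))


def random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform A/C/G/T bytes of length *n*."""
    return BASES[rng.integers(0, 4, size=n)]


def validate_acgt(seq: str, what: str = "sequence") -> None:
    """Reject empty sequences or anything outside the A/C/G/T alphabet."""
    if not seq:
        raise ValueError(f"{what} is empty")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
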