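"""Low-level nucleotide helpers shared across modules.

Sequences are handled as plain uppercase strings at module boundaries and as
uint8 code arrays (A=0, C=1, G=2, T=3; 4 = anything else) internally.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

# complement of code i; non-ACGT maps to itself (code 4)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a code array back to an uppercase string (code 4 -> N)."""
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case-preserving)."""
    return seq.translate(_COMP_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """I.i.d. uniform A/C/G/T background sequence."""
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8).astype(np.uint8))


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of a code array into an int64 (2 bits per base).

    Positions containing a non-ACGT code yield -1 so they never match.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        window = codes[i : i + n]
        out = (out << 2) | window.astype(np.int64)
        bad |= window > 3
    out[bad] = -1
    return out
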