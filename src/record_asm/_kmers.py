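"""Vectorized 2-bit k-mer encoding shared by the assembler and the mapper.

Bases are encoded A=0, C=1, G=2, T=3; N (and anything else) gets code 4 and
invalidates every k-mer window that covers it. A k-mer is packed into a
uint64 with the first base in the highest-order bits, so k <= 31.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 code array (N -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASE_BYTES[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def kmer_windows(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All length-k windows of ``codes`` as packed integers.

    Returns ``(fwd, rc, valid)`` where ``fwd[i]`` encodes codes[i:i+k],
    ``rc[i]`` its reverse complement, and ``valid[i]`` is False when the
    window contains an N.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    n = codes.size - k + 1
    if n <= 0:
        z = np.zeros(0, dtype=np.uint64)
        return z, z.copy(), np.zeros(0, dtype=bool)
    c = (codes & 3).astype(np.uint64)
    comp = c ^ np.uint64(3)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd |= c[j : j + n] << np.uint64(2 * (k - 1 - j))
        rc |= comp[j : j + n] << np.uint64(2 * j)
    is_n = np.concatenate(([0], np.cumsum(codes >= 4, dtype=np.int64)))
    valid = (is_n[k:] - is_n[:-k]) == 0
    return fwd, rc, valid


# reverse-complement of an 8-base (16-bit) chunk, for scalar k-mer flips
_RC16 = np.zeros(65536, dtype=np.uint64)
_x = np.arange(65536, dtype=np.uint64)
for _j in range(8):
    _RC16 |= (((_x >> np.uint64(2 * _j)) & np.uint64(3)) ^ np.uint64(3)) << np.uint64(
        2 * (7 - _j)
    )
del _x


def revcomp_int(kmer: int, k: int) -> int:
    """Reverse complement of a packed k-mer (scalar)."""
    nchunks = (k + 7) // 8
    y = 0
    x = kmer
    for _ in range(nchunks):
        y = (y << 16) | int(_RC16[x & 0xFFFF])
        x >>= 16
    return y >> (2 * (8 * nchunks - k))


def kmer_to_str(kmer: int, k: int) -> str:
    return "".join("ACGT"[(kmer >> (2 * (k - 1 - i))) & 3] for i in range(k))
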