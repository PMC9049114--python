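"""Vectorised 2-bit k-mer encoding and canonicalisation.

A k-mer over {A,C,G,T} is packed into a uint64 with A=0, C=1, G=2, T=3,
most-significant base first, so integer order equals lexicographic order.
Windows containing N are excluded. k is limited to 31 so codes fit in
62 bits.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i

_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_M8 = np.uint64(0x00FF00FF00FF00FF)
_M16 = np.uint64(0x0000FFFF0000FFFF)


def encode_bases(seq: str) -> np.ndarray:
    """Per-base 2-bit codes; 255 marks N (or any non-ACGT byte)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All N-free k-mer codes of *seq* with their start offsets.

    Returns (codes: uint64 array, starts: int64 array), in sequence order.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    base = encode_bases(seq)
    n = len(base)
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    nw = n - k + 1
    codes = np.zeros(nw, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        codes = (codes << two) | base[j : j + nw].astype(np.uint64)
    isn = (base == 255).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(isn)))
    valid = (cum[k:] - cum[:-k]) == 0
    starts = np.nonzero(valid)[0]
    return codes[valid], starts


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse complement of packed k-mer codes, vectorised."""
    x = (~codes) & np.uint64((1 << (2 * k)) - 1)  # 2-bit complement per base
    # reverse 2-bit groups across the full 64-bit word
    x = ((x >> np.uint64(2)) & _M2) | ((x & _M2) << np.uint64(2))
    x = ((x >> np.uint64(4)) & _M4) | ((x & _M4) << np.uint64(4))
    x = ((x >> np.uint64(8)) & _M8) | ((x & _M8) << np.uint64(8))
    x = ((x >> np.uint64(16)) & _M16) | ((x & _M16) << np.uint64(16))
    x = (x >> np.uint64(32)) | (x << np.uint64(32))
    return x >> np.uint64(64 - 2 * k)


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """min(code, revcomp(code)) per k-mer — strand-independent identity."""
    return np.minimum(codes, revcomp_codes(codes, k))


def canonical_kmer_set(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes of one sequence."""
    codes, _ = kmer_codes(seq, k)
    return np.unique(canonical_codes(codes, k))


def decode_kmer(code: int, k: int) -> str:
    out = []
    for j in range(k - 1, -1, -1):
        out.append("ACGT"[(code >> (2 * j)) & 3])
    return "".join(out)
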