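"""Low-level DNA utilities shared across the pipeline.

All sequences are uppercase strings over {A,C,G,T,N}.  Numeric encoding maps
A,C,G,T -> 0..3 and N -> 255 (invalid), which keeps k-mer packing into uint64
branch-free.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: base -> 2-bit code lookup (uint8); everything else maps to 255
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of *seq* (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode *seq* as uint8 codes (A=0,C=1,G=2,T=3, other=255)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_kmer(code: int, k: int) -> str:
    """Spell the k-mer packed in integer *code* (2 bits/base, first base high)."""
    return "".join("ACGT"[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed forward k-mer codes of every window of *seq*.

    Returns ``(codes, valid)`` where ``codes[i]`` packs ``seq[i:i+k]`` 2 bits
    per base (first base in the high bits) and ``valid[i]`` is False for
    windows containing a non-ACGT character.
    """
    base = encode(seq)
    n = len(base) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = base[j : j + n]
        valid &= window != 255
        codes = (codes << np.uint64(2)) | (window & 3).astype(np.uint64)
    return codes, valid


def rc_kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of the reverse complement of every forward window of *seq*."""
    base = encode(seq)
    n = len(base) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    comp = np.where(base == 255, 255, 3 - base).astype(np.uint8)
    codes = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k - 1, -1, -1):  # rc reads the window back to front
        window = comp[j : j + n]
        valid &= window != 255
        codes = (codes << np.uint64(2)) | (window & 3).astype(np.uint64)
    return codes, valid


def random_dna(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """i.i.d. random DNA of length *n* with GC fraction *gc*."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int((encode(a) != encode(b)).sum())


def rotate(seq: str, r: int) -> str:
    r %= len(seq)
    return seq[r:] + seq[:r]
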