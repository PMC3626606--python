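"""Low-level sequence helpers shared across modules.

All sequences are uppercase Python strings over the alphabet {A, C, G, T, N}.
``N`` is a placeholder base: it never matches anything (including another N)
in any comparison performed by this package.
"""

from __future__ import annotations

import numpy as np

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# 2-bit encoding for k-mer hashing; N (and anything else) maps to -1.
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence as an int8 array of 2-bit base codes; invalid bases are -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer code of every k-mer of ``seq``; windows containing N get -1.

    Codes are base-4 numbers with the leftmost base most significant, so two
    windows share a code iff they are the same string.
    """
    codes2 = encode(seq)
    n = codes2.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out = out * 4 + codes2[j : j + n]
    # mark windows containing an invalid base
    bad = codes2 < 0
    if bad.any():
        bad_count = np.concatenate(([0], np.cumsum(bad)))
        out[(bad_count[k:] - bad_count[:-k]) > 0] = -1
    return out


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N never matches."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length sequences")
    return sum(x != y or x == "N" for x, y in zip(a, b))


def at_fraction(seq: str) -> float:
    """A+T fraction over called bases (N excluded from both sides).

    Raises ValueError on an empty or all-N sequence, where the fraction is
    undefined.
    """
    if not seq:
        raise ValueError("A+T fraction undefined for empty sequence")
    at = seq.count("A") + seq.count("T")
    acgt = at + seq.count("C") + seq.count("G")
    if acgt == 0:
        raise ValueError("A+T fraction undefined: no called bases")
    return at / acgt
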