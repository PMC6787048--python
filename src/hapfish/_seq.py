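"""Low-level DNA sequence helpers: 2-bit encoding, k-mer codes, reverse
complements.

Everything here works on plain Python strings (A/C/G/T, uppercase) and numpy
arrays of 2-bit base codes (A=0, C=1, G=2, T=3; anything else = 4 and is
treated as invalid by the k-mer routines).
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# byte value -> 2-bit code, 4 for non-ACGT
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lowercase

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 base codes (A=0,C=1,G=2,T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (invalid codes become ``N``)."""
    return _DEC[np.minimum(codes, 4)].tobytes().decode("ascii")


def kmer_codes(base_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer integer codes over a 2-bit encoded sequence.

    Returns ``(codes, valid)`` where ``codes[i]`` encodes
    ``seq[i:i+k]`` as a 2k-bit integer and ``valid[i]`` is False when the
    window contains a non-ACGT base (its code is meaningless). Requires
    ``k <= 31``.
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    n = base_codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    b = np.minimum(base_codes, 3).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | b[j : j + n]
    bad = (base_codes >= 4).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


def rc_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement k-mer codes (vectorized)."""
    out = np.zeros_like(codes, dtype=np.uint64)
    c = codes.astype(np.uint64).copy()
    three = np.uint64(3)
    two = np.uint64(2)
    for _ in range(k):
        out = (out << two) | (three - (c & three))
        c = c >> two
    return out


def canonical_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-merged) k-mer codes: min(code, revcomp code)."""
    return np.minimum(codes, rc_kmer_codes(codes, k))


def kmer_code_to_str(code: int, k: int) -> str:
    """Decode a single k-mer integer code back to its DNA string."""
    bases = []
    c = int(code)
    for _ in range(k):
        bases.append("ACGT"[c & 3])
        c >>= 2
    return "".join(reversed(bases))


def is_acgt(seq: str) -> bool:
    """True iff the sequence consists only of A/C/G/T (uppercase)."""
    return bool(seq) and not (set(seq) - set("ACGT"))
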