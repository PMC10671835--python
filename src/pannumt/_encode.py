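"""2-bit sequence encoding and k-mer key construction shared by the aligners.

A, C, G, T map to 0..3; every other IUPAC code maps to :data:`AMBIG` (4) and
is excluded from seeding/k-mer windows but tolerated in sequences.
"""

from __future__ import annotations

import numpy as np

AMBIG = 4

IUPAC_CODES = set("ACGTNRYSWKMBDHV")

_COMP = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

_LUT = np.full(256, AMBIG, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lowercase


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A,C,G,T -> 0..3, other IUPAC -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def kmer_keys(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling integer keys for every k-window of an encoded sequence.

    Returns ``(keys, valid)`` of length ``len(codes) - k + 1``; ``valid`` is
    False for windows containing any non-ACGT base (their key is undefined).
    Keys fit int64 for k <= 31.
    """
    if k > 31:
        raise ValueError("k-mer keys support k <= 31")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    c = codes.astype(np.int64)
    keys = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for t in range(k):
        win = c[t : t + n]
        keys = (keys << 2) | (win & 3)
        bad |= win == AMBIG
    return keys, ~bad
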