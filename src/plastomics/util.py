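"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

# 2-bit base codes; anything non-ACGT maps to 4 (ambiguous)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rotate(seq: str, offset: int) -> str:
    """Rotate a circular sequence so old position ``offset`` becomes position 0."""
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def encode_bases(seq: str) -> np.ndarray:
    """Encode DNA into uint8 codes 0..3 (A,C,G,T); 4 for ambiguity codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def complement_codes(codes: np.ndarray) -> np.ndarray:
    """Complement on the 0..3 encoding; ambiguous (4) stays ambiguous."""
    out = 3 - codes
    out[codes == 4] = 4
    return out
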