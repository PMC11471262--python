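"""RNA alphabet encoding shared across the package.

Bases are coded A=0, C=1, G=2, U=3.  'T' is silently normalized to 'U';
any other character is rejected (no IUPAC ambiguity codes).  The six
canonical pair types are ordered AU, CG, GC, GU, UA, UG.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
BASE_INDEX["T"] = BASE_INDEX["U"]

PAIR_TYPES = ("AU", "CG", "GC", "GU", "UA", "UG")

# PAIR_TYPE_TABLE[b1, b2] = pair-type index, or -1 if not canonical
PAIR_TYPE_TABLE = -np.ones((4, 4), dtype=np.int8)
for _k, (_b1, _b2) in enumerate(PAIR_TYPES):
    PAIR_TYPE_TABLE[BASE_INDEX[_b1], BASE_INDEX[_b2]] = _k


class SequenceError(ValueError):
    """Raised for sequences containing characters outside ACGU/T."""


def normalize(seq: str) -> str:
    """Uppercase and map T to U; raise ``SequenceError`` on anything else."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(BASES)
    if bad:
        raise SequenceError(
            f"non-ACGU character(s) {sorted(bad)} in sequence (after U/T normalization)"
        )
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as an int8 array (A=0, C=1, G=2, U=3)."""
    s = normalize(seq)
    return np.array([BASE_INDEX[c] for c in s], dtype=np.int8)


def decode(codes) -> str:
    return "".join(BASES[int(c)] for c in codes)


def pair_type(b1: int, b2: int) -> int:
    """Pair-type index of coded bases, or -1 if non-canonical."""
    return int(PAIR_TYPE_TABLE[b1, b2])
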