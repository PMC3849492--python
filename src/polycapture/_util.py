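"""Small shared helpers: rounding, DNA alphabet, reverse complement."""

from __future__ import annotations

import decimal
import math

import numpy as np

DNA = "ACGT"
DNA_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# uint8 lookup table for complementing byte arrays
_COMP_TABLE = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCAtgca"):
    _COMP_TABLE[_a] = _b

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of a uint8 DNA byte array."""
    return _COMP_TABLE[arr][::-1]


def seq_to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def arr_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (table convention; Python's
    built-in round is banker's rounding).  Decimal-based so that printed
    ties like -18.65 behave as a reader of a table would expect."""
    if math.isnan(x) or math.isinf(x):
        return x
    quantum = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(
        quantum, rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


def is_transition(ref: str, alt: str) -> bool:
    pair = {ref, alt}
    return pair <= PURINES or pair <= PYRIMIDINES
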