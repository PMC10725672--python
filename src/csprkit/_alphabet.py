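"""Shared base-encoding tables.

Bases are encoded A=0, C=1, G=2, T=3, N=4.  All numeric code paths in the
package use this encoding; ``N`` never enters a classified context.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

# str.translate table for complementation (upper-case alphabet only).
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# code -> complement code; N maps to itself.
COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

# ASCII byte -> code lookup (A/C/G/T/N upper or lower); 255 marks invalid.
_BYTE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _BYTE_TO_CODE[ord(_b)] = _i
    _BYTE_TO_CODE[ord(_b.lower())] = _i

CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


class DnaAlphabetError(ValueError):
    """Raised when a sequence contains a character outside {A,C,G,T,N}."""

    def __init__(self, char: str, position: int, record: str | None = None):
        self.char = char
        self.position = position
        self.record = record
        where = f" in record {record!r}" if record else ""
        super().__init__(
            f"invalid DNA character {char!r} at position {position}{where}"
        )


def encode(seq: str, record: str | None = None) -> np.ndarray:
    """Encode a DNA string to uint8 codes, validating the alphabet.

    Raises :class:`DnaAlphabetError` naming the 0-based offset of the first
    invalid character.
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _BYTE_TO_CODE[raw]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise DnaAlphabetError(seq[pos], pos, record)
    return codes


def decode(codes: np.ndarray) -> str:
    return CODE_TO_BASE[codes].tobytes().decode("ascii")


def complement_char(base: str) -> str:
    return base.translate(_COMPLEMENT)
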