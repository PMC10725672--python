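"""Core intrastrand-symmetry operations on raw DNA.

Chargaff's second parity rule (CSPR) states that within a single, sufficiently
long DNA strand the count of any k-mer is nearly equal to the count of its
reverse complement (for k=1 this is G ~ C and A ~ T).  This module provides
the primitives the rest of the package is built on: reverse complementation,
the percentage-difference statistic used throughout the reports, whole-sequence
k-mer parity tables, and sliding-window GC/AT skew profiles.

Sequences are plain Python strings over {A,C,G,T,N}; they are validated and
upper-cased at the I/O boundary (:mod:`csprkit.io`).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from ._alphabet import COMP_CODE, _COMPLEMENT, encode

__all__ = [
    "reverse_complement",
    "percentage_difference",
    "round_half_up",
    "KmerParityRow",
    "kmer_parity_table",
    "SkewRow",
    "skew_profile",
]


def reverse_complement(seq: str) -> str:
    """Reverse complement of ``seq`` (A<->T, C<->G, N<->N, order reversed).

    An involution on valid sequences.  Raises
    :class:`~csprkit._alphabet.DnaAlphabetError` on any character outside
    {A,C,G,T,N} (case-insensitive), naming the offending position.
    """
    encode(seq)  # validation only; keeps the error message centralized
    return seq.upper().translate(_COMPLEMENT)[::-1]


def percentage_difference(a: float, b: float) -> float:
    """Signed percentage difference ``200 * (a - b) / (a + b)``.

    This is the statistic used to compare a count with the count of its
    reverse-complement partner; it is antisymmetric and bounded in
    [-200, 200].  Returns NaN when ``a + b == 0`` (rendered as ``NA`` in
    reports).  Counts must be non-negative.
    """
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    total = a + b
    if total == 0:
        return math.nan
    return 200.0 * (a - b) / total


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (report rule).

    NaN passes through (undefined values stay undefined).
    """
    if isinstance(x, float) and math.isnan(x):
        return x
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class KmerParityRow:
    """One canonical reverse-complement k-mer pair and its counts.

    ``kmer`` is the lexicographically smaller member; ``diff_pct`` is the
    absolute percentage difference rounded to 2 decimals (NaN when both
    counts are zero).
    """

    kmer: str
    rc_kmer: str
    count_fwd: int
    count_rc: int
    diff_pct: float
    self_complementary: bool


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Codes of all valid (N-free) length-k windows as base-4 integers."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        window = codes[i : i + n]
        valid &= window != 4
        out = out * 4 + window
    return out[valid]


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def _rc_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = rc * 4 + (3 - code % 4)
        code //= 4
    return rc


def kmer_parity_table(seq: str, k: int) -> list[KmerParityRow]:
    """Count all overlapping k-mers of ``seq`` and pair them by reverse
    complement.

    Windows containing N are skipped.  Exactly one row is emitted per
    canonical pair (smaller member first) plus one row per self-complementary
    k-mer, i.e. ``(4**k + s) / 2`` rows where ``s`` is the number of
    self-complementary k-mers (0 for odd k).
    """
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in 1..8, got {k}")
    codes = encode(seq)
    counts = np.bincount(_kmer_codes(codes, k), minlength=4**k)
    rows: list[KmerParityRow] = []
    for code in range(4**k):
        rc = _rc_code(code, k)
        if code > rc:
            continue
        fwd, rev = int(counts[code]), int(counts[rc])
        if code == rc:
            rows.append(
                KmerParityRow(_decode_kmer(code, k), _decode_kmer(rc, k),
                              fwd, fwd, 0.0 if fwd else math.nan, True)
            )
        else:
            diff = round_half_up(abs(percentage_difference(fwd, rev)))
            rows.append(
                KmerParityRow(_decode_kmer(code, k), _decode_kmer(rc, k),
                              fwd, rev, diff, False)
            )
    return rows


@dataclass(frozen=True)
class SkewRow:
    """GC/AT skew of one window; coordinates are 1-based inclusive.

    Sign convention: ``gc_skew = (G - C) / (G + C)`` and
    ``at_skew = (A - T) / (A + T)``; NaN when the denominator is zero.
    """

    window_start: int
    window_end: int
    gc_skew: float
    at_skew: float


def skew_profile(seq: str, window: int, step: int | None = None) -> list[SkewRow]:
    """Sliding-window GC and AT skew along ``seq``.

    A trailing partial window is emitted with its true end coordinate.
    N bases are ignored in the counts.  Skews are localized deviations from
    CSPR: a long CSPR-compliant strand has both skews near zero on average,
    with alternating-sign segments locally.
    """
    if window < 1 or (step is not None and step < 1):
        raise ValueError("window and step must be >= 1")
    step = step or window
    codes = encode(seq)
    rows: list[SkewRow] = []
    for start in range(0, len(seq), step):
        chunk = codes[start : start + window]
        if chunk.size == 0:
            break
        counts = np.bincount(chunk, minlength=5)
        a, c, g, t = (int(counts[i]) for i in range(4))
        gc = (g - c) / (g + c) if g + c else math.nan
        at = (a - t) / (a + t) if a + t else math.nan
        rows.append(SkewRow(start + 1, start + chunk.size, gc, at))
        if start + chunk.size >= len(seq):
            break
    return rows
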