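"""Trinucleotide-context SNV classification and reverse-complement parity.

A single-base substitution X->Y read on the forward strand together with its
immediate 5' and 3' flanks N defines a *directed* contextual class NXN>NYN.
There are 4 x 4 x 3 x 4 = 192 directed classes.  Because a variant database
records an interchange rather than an ancestral direction, classes are folded
by ref/alt interchange into 96 *undirected* classes {NXN<->NYN}.  Reverse
complementation maps undirected classes onto each other; exactly 8 classes are
their own image (right flank = complement of left flank and alt = complement
of ref), leaving 44 comparison pairs.  Under intrastrand DNA symmetry the two
members of every comparison pair occur in nearly equal numbers in a
population-scale variant set; the parity report quantifies this with the
percentage difference 200*(A-B)/(A+B).

No pyrimidine-anchored folding (COSMIC-style 96 types) is applied: collapsing
C>T with G>A would erase precisely the parity this analysis measures.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
import pandas as pd

from ._alphabet import complement_char
from .seqsym import percentage_difference, reverse_complement, round_half_up
from .variants import (SNV, FilterConfig, Rejection, ReferenceMismatchError,
                       SpectrumTable, VariantRecord, VariantTable)

__all__ = ["ContextClass", "PairingScheme", "enumerate_scheme",
           "classify_snv", "tabulate_snv_spectrum", "parity_report"]

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

UNDIRECTED_SEP = "<->"


def undirected_key(triplet_a: str, triplet_b: str) -> str:
    """Canonical key of the interchange class {triplet_a <-> triplet_b}."""
    lo, hi = sorted((triplet_a, triplet_b))
    return f"{lo}{UNDIRECTED_SEP}{hi}"


def key_triplets(key: str) -> tuple[str, str]:
    a, b = key.split(UNDIRECTED_SEP)
    return a, b


@dataclass(frozen=True)
class ContextClass:
    """A directed contextual substitution class NXN>NYN."""

    left: str
    ref: str
    alt: str
    right: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for b in (self.left, self.ref, self.alt, self.right):
            if b not in "ACGT":
                raise ValueError(f"invalid base {b!r}")

    @property
    def ref_triplet(self) -> str:
        return self.left + self.ref + self.right

    @property
    def alt_triplet(self) -> str:
        return self.left + self.alt + self.right

    @property
    def directed_key(self) -> str:
        return f"{self.ref_triplet}>{self.alt_triplet}"

    @property
    def undirected_key(self) -> str:
        return undirected_key(self.ref_triplet, self.alt_triplet)


def rc_undirected(key: str) -> str:
    """Reverse-complement image of an undirected class key (an involution)."""
    a, b = key_triplets(key)
    return undirected_key(reverse_complement(a), reverse_complement(b))


@dataclass(frozen=True)
class PairingScheme:
    """The closed comparison structure over the 96 undirected classes.

    ``comparison_pairs`` lists the 44 {class, rc-class} pairs (canonical
    member first); ``self_complementary`` the 8 fixed points of reverse
    complementation.  ``pyrimidine_oriented_pairs`` is the subset of pairs
    with an unambiguous strand orientation — one member has both interchange
    bases pyrimidine, the other both purine — used for strand-bias
    estimation.
    """

    undirected_classes: tuple[str, ...]
    comparison_pairs: tuple[tuple[str, str], ...]
    self_complementary: tuple[str, ...]
    pyrimidine_oriented_pairs: tuple[tuple[str, str], ...]

    @property
    def n_directed(self) -> int:
        return 2 * len(self.undirected_classes)

    def index(self) -> dict[str, int]:
        return {k: i for i, k in enumerate(self.undirected_classes)}


def _middle_bases(key: str) -> frozenset[str]:
    a, b = key_triplets(key)
    return frozenset((a[1], b[1]))


def enumerate_scheme() -> PairingScheme:
    """Enumerate the 192 directed / 96 undirected classes and pair them by
    reverse complement (44 pairs + 8 self-complementary, deterministic
    order)."""
    undirected: set[str] = set()
    for left in "ACGT":
        for ref in "ACGT":
            for alt in "ACGT":
                if alt == ref:
                    continue
                for right in "ACGT":
                    undirected.add(
                        ContextClass(left, ref, alt, right).undirected_key)
    classes = tuple(sorted(undirected))
    pairs, selfc, oriented = [], [], []
    for key in classes:
        rc = rc_undirected(key)
        if rc == key:
            selfc.append(key)
        elif key < rc:
            pairs.append((key, rc))
            mid = _middle_bases(key)
            if mid <= PYRIMIDINES:
                oriented.append((key, rc))
            elif mid <= PURINES:
                oriented.append((rc, key))
    return PairingScheme(classes, tuple(pairs), tuple(selfc), tuple(oriented))


# cached module-level scheme and fast lookup table -------------------------

_SCHEME: PairingScheme | None = None
_UND_INDEX: np.ndarray | None = None  # (l*4+ref)*4+alt)*4+right -> class index


def default_scheme() -> PairingScheme:
    global _SCHEME
    if _SCHEME is None:
        _SCHEME = enumerate_scheme()
    return _SCHEME


def _und_index() -> np.ndarray:
    global _UND_INDEX
    if _UND_INDEX is None:
        scheme = default_scheme()
        idx = scheme.index()
        table = np.full(256, -1, dtype=np.int16)
        code = {b: i for i, b in enumerate("ACGT")}
        for left in "ACGT":
            for ref in "ACGT":
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    for right in "ACGT":
                        key = ContextClass(left, ref, alt, right).undirected_key
                        flat = ((code[left] * 4 + code[ref]) * 4
                                + code[alt]) * 4 + code[right]
                        table[flat] = idx[key]
        _UND_INDEX = table
    return _UND_INDEX


def classify_snv(variant: VariantRecord, genome,
                 filters: FilterConfig | None = None
                 ) -> Union[str, Rejection]:
    """Classify one SNV into its undirected contextual class.

    The context is always read from the forward (top) strand of the
    reference at pos-1, pos, pos+1.  Returns the undirected class key, or a
    :class:`Rejection` reason.  In strict mode a REF/genome disagreement
    raises :class:`ReferenceMismatchError` instead of rejecting.
    """
    filters = filters or FilterConfig()
    if variant.chrom in filters.exclude_chroms:
        return Rejection.chromosome_excluded
    if variant.chrom not in genome:
        return Rejection.chromosome_unknown
    if variant.filter not in filters.accepted_filters:
        return Rejection.filter_failed
    if filters.require_validated and not variant.validated:
        return Rejection.not_validated
    if not variant.is_snv:
        return Rejection.not_snv
    codes = genome.codes(variant.chrom)
    pos = variant.pos
    if pos < 2 or pos > codes.size - 1:
        return Rejection.edge_of_sequence
    left, ref, right = (int(codes[pos - 2]), int(codes[pos - 1]),
                        int(codes[pos]))
    if 4 in (left, right):
        return Rejection.context_contains_n
    if ref == 4 or "ACGT"[ref] != variant.ref:
        if ref != 4 and filters.strict:
            raise ReferenceMismatchError(
                f"{variant.chrom}:{pos} VCF REF {variant.ref} != genome "
                f"{'ACGT'[ref]}")
        return (Rejection.context_contains_n if ref == 4
                else Rejection.reference_mismatch)
    return ContextClass("ACGT"[left], variant.ref, variant.alt,
                        "ACGT"[right]).undirected_key


def _tabulate_table_fast(table: VariantTable, genome,
                         filters: FilterConfig) -> SpectrumTable:
    """Vectorized classification of a columnar SNV table.

    The table stores alt codes only; REF is read from the genome, so
    reference mismatches cannot occur on this path (the simulator draws
    alleles from the same genome).
    """
    scheme = default_scheme()
    lookup = _und_index()
    counts = np.zeros(len(scheme.undirected_classes), dtype=np.int64)
    rejections: Counter = Counter()

    # deduplicate on (chrom, pos, kind, base); first occurrence wins
    packed = (((table.chrom_idx.astype(np.int64) * 4 + table.kind) << 34)
              + (table.pos << 2) + (table.base.astype(np.int64) & 3))
    _, first = np.unique(packed, return_index=True)
    keep = np.zeros(len(table), dtype=bool)
    keep[first] = True
    n_dup = int((~keep).sum())
    if n_dup:
        rejections[Rejection.duplicate] += n_dup

    # rejection precedence mirrors classify_snv: chromosome checks, then
    # the validation flag, then the record shape, then sequence context
    for ci, name in enumerate(table.chrom_names):
        mask = keep & (table.chrom_idx == ci)
        if not mask.any():
            continue
        n_chrom = int(mask.sum())
        if name in filters.exclude_chroms:
            rejections[Rejection.chromosome_excluded] += n_chrom
            continue
        if name not in genome:
            rejections[Rejection.chromosome_unknown] += n_chrom
            continue
        if filters.require_validated:
            bad = mask & ~table.validated
            n_bad = int(bad.sum())
            if n_bad:
                rejections[Rejection.not_validated] += n_bad
                mask = mask & table.validated
        n_not_snv = int((mask & (table.kind != SNV)).sum())
        if n_not_snv:
            rejections[Rejection.not_snv] += n_not_snv
            mask = mask & (table.kind == SNV)
        codes = genome.codes(name)
        pos = table.pos[mask]
        alt = table.base[mask]
        edge = (pos < 2) | (pos > codes.size - 1)
        if edge.any():
            rejections[Rejection.edge_of_sequence] += int(edge.sum())
            pos, alt = pos[~edge], alt[~edge]
        left = codes[pos - 2].astype(np.int64)
        ref = codes[pos - 1].astype(np.int64)
        right = codes[pos].astype(np.int64)
        has_n = (left == 4) | (ref == 4) | (right == 4)
        if has_n.any():
            rejections[Rejection.context_contains_n] += int(has_n.sum())
            ok = ~has_n
            left, ref, right, alt = left[ok], ref[ok], right[ok], alt[ok]
        flat = ((left * 4 + ref) * 4 + alt) * 4 + right
        counts += np.bincount(lookup[flat],
                              minlength=len(scheme.undirected_classes))
    return SpectrumTable(
        dict(zip(scheme.undirected_classes, counts.tolist())), rejections)


def tabulate_snv_spectrum(variants: "Iterable[VariantRecord] | VariantTable",
                          genome, filters: FilterConfig | None = None
                          ) -> SpectrumTable:
    """Count accepted SNVs into the 96 undirected classes.

    Accepts either a stream of :class:`VariantRecord` (e.g. from
    :func:`csprkit.io.read_vcf`) or a columnar :class:`VariantTable` (fast
    vectorized path).  Duplicates on (chrom, pos, ref, alt) are counted
    once; every input record lands in exactly one class or one rejection
    tally.
    """
    filters = filters or FilterConfig()
    if isinstance(variants, VariantTable):
        return _tabulate_table_fast(variants, genome, filters)
    scheme = default_scheme()
    counts = {key: 0 for key in scheme.undirected_classes}
    rejections: Counter = Counter()
    seen: set[tuple] = set()
    for variant in variants:
        dedup = (variant.chrom, variant.pos, variant.ref, variant.alt)
        if dedup in seen:
            rejections[Rejection.duplicate] += 1
            continue
        seen.add(dedup)
        result = classify_snv(variant, genome, filters)
        if isinstance(result, Rejection):
            rejections[result] += 1
        else:
            counts[result] += 1
    return SpectrumTable(counts, rejections)


def parity_report(spectrum: SpectrumTable,
                  scheme: PairingScheme | None = None,
                  sort: bool = False) -> pd.DataFrame:
    """Table-1-style parity report: 44 comparison-pair rows followed by the
    8 self-complementary single-class rows.

    ``diff_pct`` is the absolute percentage difference between the pair's
    counts, rounded half-up to 2 decimals (NaN when both counts are zero);
    ``diff_pct_raw`` keeps the signed full-precision value.  With ``sort``
    the pair rows are ordered by descending ``diff_pct``.
    """
    scheme = scheme or default_scheme()
    for key in scheme.undirected_classes:
        if key not in spectrum.counts:
            raise KeyError(f"class {key} missing from spectrum")
    rows = []
    for key, rc_key in scheme.comparison_pairs:
        t1, t2 = key_triplets(key)
        r1, r2 = key_triplets(rc_key)
        a, b = spectrum.counts[key], spectrum.counts[rc_key]
        raw = percentage_difference(a, b)
        rows.append(dict(
            triplet_ref=t1, triplet_alt=t2, x=t1[1], y=t2[1],
            count=a, fraction_pct=spectrum.fraction_pct(key),
            rc_triplet_ref=r1, rc_triplet_alt=r2, rc_x=r1[1], rc_y=r2[1],
            rc_count=b, rc_fraction_pct=spectrum.fraction_pct(rc_key),
            diff_pct=round_half_up(abs(raw)) if not math.isnan(raw) else raw,
            diff_pct_raw=raw, self_complementary=False))
    if sort:
        rows.sort(key=lambda r: (math.isnan(r["diff_pct"]), -r["diff_pct"]
                                 if not math.isnan(r["diff_pct"]) else 0))
    for key in scheme.self_complementary:
        t1, t2 = key_triplets(key)
        rows.append(dict(
            triplet_ref=t1, triplet_alt=t2, x=t1[1], y=t2[1],
            count=spectrum.counts[key],
            fraction_pct=spectrum.fraction_pct(key),
            rc_triplet_ref=None, rc_triplet_alt=None, rc_x=None, rc_y=None,
            rc_count=None, rc_fraction_pct=math.nan,
            diff_pct=math.nan, diff_pct_raw=math.nan,
            self_complementary=True))
    frame = pd.DataFrame(rows)
    frame.insert(0, "no", range(1, len(frame) + 1))
    return frame
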