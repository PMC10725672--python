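"""Single-base indel classification by flanking context and parity pairing.

A length-1 insertion or deletion of base B with forward-strand flanks L and R
defines the class L-R<->LBR (a gap aligned against B).  There are 4x4x4 = 64
classes; reverse complementation maps LBR -> rc(R) comp(B) rc(L) with no fixed
points, giving 32 comparison pairs.  A pair is *alignable* — the indel's
placement within the local alignment is unambiguous — exactly when B differs
from both flanks (36 classes, 18 pairs).  When B equals a neighbouring base
the event sits in a homopolymer run and the gap position is not unique, so the
remaining 14 pairs are reported with counts but flagged non-comparable.

Insertions and deletions of the same (L, B, R) fall in the same class; the
tabulator keeps separate insertion/deletion sub-counts as well.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
import pandas as pd

from ._alphabet import complement_char
from .seqsym import percentage_difference, round_half_up
from .variants import (DEL, INS, FilterConfig, Rejection,
                       ReferenceMismatchError, SpectrumTable, VariantRecord,
                       VariantTable)

__all__ = ["IndelClass", "IndelPairingScheme", "enumerate_indel_scheme",
           "classify_indel", "tabulate_indel_spectrum", "IndelSpectrumResult"]


def indel_key(left: str, base: str, right: str) -> str:
    return f"{left}-{right}<->{left}{base}{right}"


@dataclass(frozen=True)
class IndelClass:
    """Context class of a single-base indel: gap/base B between L and R."""

    left: str
    indel_base: str
    right: str

    def __post_init__(self):
        for b in (self.left, self.indel_base, self.right):
            if b not in "ACGT":
                raise ValueError(f"invalid base {b!r}")

    @property
    def key(self) -> str:
        return indel_key(self.left, self.indel_base, self.right)

    @property
    def alignable(self) -> bool:
        return (self.indel_base != self.left
                and self.indel_base != self.right)

    @property
    def rc(self) -> "IndelClass":
        return IndelClass(complement_char(self.right),
                          complement_char(self.indel_base),
                          complement_char(self.left))


@dataclass(frozen=True)
class IndelPairingScheme:
    """64 classes, 32 reverse-complement pairs, 18 alignable / 14 ambiguous."""

    classes: tuple[IndelClass, ...]
    pairs: tuple[tuple[IndelClass, IndelClass], ...]

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(c.key for c in self.classes)

    @property
    def alignable_pairs(self) -> tuple[tuple[IndelClass, IndelClass], ...]:
        return tuple(p for p in self.pairs if p[0].alignable)

    @property
    def ambiguous_pairs(self) -> tuple[tuple[IndelClass, IndelClass], ...]:
        return tuple(p for p in self.pairs if not p[0].alignable)


_SCHEME: IndelPairingScheme | None = None


def enumerate_indel_scheme() -> IndelPairingScheme:
    """Enumerate all 64 (L, B, R) classes and pair them by reverse
    complement (deterministic order, canonical member = smaller key)."""
    classes = tuple(IndelClass(l, b, r)
                    for l in "ACGT" for b in "ACGT" for r in "ACGT")
    pairs = tuple((c, c.rc) for c in classes if c.key < c.rc.key)
    return IndelPairingScheme(classes, pairs)


def default_indel_scheme() -> IndelPairingScheme:
    global _SCHEME
    if _SCHEME is None:
        _SCHEME = enumerate_indel_scheme()
    return _SCHEME


def classify_indel(variant: VariantRecord, genome,
                   filters: FilterConfig | None = None
                   ) -> Union[str, Rejection]:
    """Classify one VCF-anchored length-1 indel into its (L, B, R) class.

    Deletion (REF ``LB``, ALT ``L``): B is the deleted base, R the reference
    base after it.  Insertion (REF ``L``, ALT ``LB``): B is inserted between
    anchor L and the next reference base R.  Both flanks are read from the
    forward strand; indels are taken as given, without re-left-alignment, so
    homopolymer-adjacent events land in ambiguous classes by construction.
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
    if not variant.is_length1_indel:
        return Rejection.not_single_base_indel
    ref, alt = variant.ref, variant.alt
    if ref[0] != alt[0]:
        return Rejection.malformed_indel
    codes = genome.codes(variant.chrom)
    pos = variant.pos  # 1-based anchor
    if pos < 1:
        return Rejection.malformed_indel
    if len(ref) == 2:  # deletion of ref[1]
        # need anchor, deleted base and the base after it
        if pos + 2 > codes.size:
            return Rejection.edge_of_sequence
        genome_ref = "ACGTN"[codes[pos - 1]] + "ACGTN"[codes[pos]]
        right_code = int(codes[pos + 1])
        left, base = ref[0], ref[1]
    else:  # insertion of alt[1] between pos and pos+1
        if pos + 1 > codes.size:
            return Rejection.edge_of_sequence
        genome_ref = "ACGTN"[codes[pos - 1]]
        right_code = int(codes[pos])
        left, base = ref[0], alt[1]
    if "N" in genome_ref or right_code == 4:
        return Rejection.context_contains_n
    if genome_ref != ref:
        if filters.strict:
            raise ReferenceMismatchError(
                f"{variant.chrom}:{pos} VCF REF {ref} != genome {genome_ref}")
        return Rejection.reference_mismatch
    return indel_key(left, base, "ACGT"[right_code])


@dataclass
class IndelSpectrumResult:
    """Counts over the 64 classes plus the 32-pair parity table.

    ``parity`` has one row per reverse-complement pair; ``diff_pct`` is
    computed only for alignable pairs (NaN and ``comparable=False``
    otherwise — the gap placement is ambiguous, so count parity between the
    two members is not a meaningful alignment statistic).
    """

    spectrum: SpectrumTable
    insertions: dict[str, int]
    deletions: dict[str, int]
    parity: pd.DataFrame


def _parity_frame(counts: dict[str, int],
                  scheme: IndelPairingScheme) -> pd.DataFrame:
    rows = []
    for c, rc in scheme.pairs:
        a, b = counts[c.key], counts[rc.key]
        if c.alignable:
            raw = percentage_difference(a, b)
            diff = round_half_up(abs(raw)) if not math.isnan(raw) else raw
        else:
            raw = diff = math.nan
        rows.append(dict(key=c.key, rc_key=rc.key, count=a, rc_count=b,
                         alignable=c.alignable, comparable=c.alignable,
                         diff_pct=diff, diff_pct_raw=raw))
    frame = pd.DataFrame(rows)
    frame.insert(0, "no", range(1, len(frame) + 1))
    return frame


def _tabulate_table_fast(table: VariantTable, genome,
                         filters: FilterConfig, scheme: IndelPairingScheme
                         ) -> IndelSpectrumResult:
    keys = scheme.keys
    key_of_flat = np.empty(64, dtype=object)
    for i, (l, b, r) in enumerate((l, b, r) for l in range(4)
                                  for b in range(4) for r in range(4)):
        key_of_flat[i] = indel_key("ACGT"[l], "ACGT"[b], "ACGT"[r])
    counts = np.zeros(64, dtype=np.int64)
    ins_counts = np.zeros(64, dtype=np.int64)
    rejections: Counter = Counter()

    packed = (((table.chrom_idx.astype(np.int64) * 4 + table.kind) << 34)
              + (table.pos << 2) + (table.base.astype(np.int64) & 3))
    _, first = np.unique(packed, return_index=True)
    keep = np.zeros(len(table), dtype=bool)
    keep[first] = True
    n_dup = int((~keep).sum())
    if n_dup:
        rejections[Rejection.duplicate] += n_dup
    # rejection precedence mirrors classify_indel: chromosome checks, then
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
        n_other = int((mask & (table.kind == 0)).sum())
        if n_other:
            rejections[Rejection.not_single_base_indel] += n_other
            mask = mask & (table.kind != 0)
        codes = genome.codes(name)
        for kind in (DEL, INS):
            sub = mask & (table.kind == kind)
            if not sub.any():
                continue
            pos = table.pos[sub]
            base = table.base[sub].astype(np.int64)
            # deletion: L=codes[pos-1], B=base(=codes[pos]), R=codes[pos+1]
            # insertion: L=codes[pos-1], B=base, R=codes[pos]
            r_off = 1 if kind == DEL else 0
            edge = pos + r_off > codes.size - 1
            if edge.any():
                rejections[Rejection.edge_of_sequence] += int(edge.sum())
                pos, base = pos[~edge], base[~edge]
            left = codes[pos - 1].astype(np.int64)
            right = codes[pos + r_off].astype(np.int64)
            has_n = (left == 4) | (right == 4) | (base == 4)
            if kind == DEL:
                has_n |= codes[pos] == 4
            if has_n.any():
                rejections[Rejection.context_contains_n] += int(has_n.sum())
                ok = ~has_n
                left, base, right = left[ok], base[ok], right[ok]
            flat = (left * 4 + base) * 4 + right
            binc = np.bincount(flat, minlength=64)
            counts += binc
            if kind == INS:
                ins_counts += binc

    count_map = {key_of_flat[i]: int(counts[i]) for i in range(64)}
    ins_map = {key_of_flat[i]: int(ins_counts[i]) for i in range(64)}
    del_map = {k: count_map[k] - ins_map[k] for k in count_map}
    ordered = {k: count_map[k] for k in keys}
    spectrum = SpectrumTable(ordered, rejections)
    return IndelSpectrumResult(spectrum, ins_map, del_map,
                               _parity_frame(ordered, scheme))


def tabulate_indel_spectrum(variants: "Iterable[VariantRecord] | VariantTable",
                            genome, filters: FilterConfig | None = None
                            ) -> IndelSpectrumResult:
    """Tabulate length-1 indels into the 64 context classes and build the
    32-pair parity table (18 alignable pairs compared, 14 reported
    non-comparable)."""
    filters = filters or FilterConfig()
    scheme = default_indel_scheme()
    if isinstance(variants, VariantTable):
        return _tabulate_table_fast(variants, genome, filters, scheme)
    counts = {key: 0 for key in scheme.keys}
    ins: Counter = Counter()
    dels: Counter = Counter()
    rejections: Counter = Counter()
    seen: set[tuple] = set()
    for variant in variants:
        dedup = (variant.chrom, variant.pos, variant.ref, variant.alt)
        if dedup in seen:
            rejections[Rejection.duplicate] += 1
            continue
        seen.add(dedup)
        result = classify_indel(variant, genome, filters)
        if isinstance(result, Rejection):
            rejections[result] += 1
        else:
            counts[result] += 1
            (ins if len(variant.alt) == 2 else dels)[result] += 1
    spectrum = SpectrumTable(counts, rejections)
    return IndelSpectrumResult(spectrum, dict(ins), dict(dels),
                               _parity_frame(counts, scheme))
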