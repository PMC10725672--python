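"""Variant containers, filtering policy, and rejection bookkeeping.

Two representations are used:

* :class:`VariantRecord` — one parsed VCF row (after multi-allelic splitting),
  the unit the classifiers operate on.  Positions are 1-based, as in VCF.
* :class:`VariantTable` — a columnar, numpy-backed set of variants produced by
  the simulator.  It serializes to VCF and iterates as ``VariantRecord``; the
  spectrum tabulators also accept it directly and use a vectorized
  classification path, which is what makes dbSNP-scale simulations practical.

Every record fed to a tabulator is accounted for exactly once: either it
increments one substitution/indel class or it increments one
:class:`Rejection` tally.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import numpy as np

from ._alphabet import decode

__all__ = ["VariantRecord", "VariantTable", "FilterConfig", "Rejection",
           "SNV", "DEL", "INS"]

# VariantTable.kind codes
SNV, DEL, INS = 0, 1, 2


class Rejection(str, Enum):
    """Machine-readable reasons a record was not classified."""

    chromosome_excluded = "chromosome_excluded"
    chromosome_unknown = "chromosome_unknown"
    filter_failed = "filter_failed"
    not_validated = "not_validated"
    edge_of_sequence = "edge_of_sequence"
    context_contains_n = "context_contains_N"
    reference_mismatch = "reference_mismatch"
    duplicate = "duplicate"
    not_snv = "not_snv"
    not_single_base_indel = "not_single_base_indel"
    malformed_indel = "malformed_indel"
    malformed = "malformed"


class ReferenceMismatchError(ValueError):
    """Raised in strict mode when a variant's REF disagrees with the genome."""


@dataclass(frozen=True)
class VariantRecord:
    """One variant call: 1-based position, alleles on the forward strand."""

    chrom: str
    pos: int
    ref: str
    alt: str
    filter: str = "."
    validated: bool = True

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_length1_indel(self) -> bool:
        return (len(self.ref), len(self.alt)) in ((2, 1), (1, 2))


@dataclass
class FilterConfig:
    """Record-acceptance policy applied by the tabulators.

    Defaults mirror a sex-chromosome-excluding, PASS-only analysis of a
    variant dump counted once from the top strand.  ``require_validated``
    is off by default: the validation flag is database-specific and plain
    VCFs without it should pass.
    """

    exclude_chroms: frozenset[str] = frozenset({"X", "Y", "chrX", "chrY"})
    accepted_filters: frozenset[str] = frozenset({"PASS", "."})
    require_validated: bool = False
    strict: bool = False

    def __post_init__(self):
        self.exclude_chroms = frozenset(self.exclude_chroms)
        self.accepted_filters = frozenset(self.accepted_filters)


@dataclass
class VariantTable:
    """Columnar variant set (simulator output).

    ``pos`` stores the 1-based VCF POS (anchor base for indels).  ``base``
    holds the SNV alt code, the deleted base code (the base at POS+1), or
    the inserted base code, depending on ``kind``.
    """

    chrom_names: list[str]
    chrom_idx: np.ndarray  # int32
    pos: np.ndarray        # int64, 1-based
    kind: np.ndarray       # int8: SNV / DEL / INS
    base: np.ndarray       # uint8 base code, meaning depends on kind
    validated: np.ndarray  # bool

    def __len__(self) -> int:
        return self.pos.size

    def sort(self) -> "VariantTable":
        order = np.lexsort((self.kind, self.pos, self.chrom_idx))
        return VariantTable(self.chrom_names, self.chrom_idx[order],
                            self.pos[order], self.kind[order],
                            self.base[order], self.validated[order])

    def _alleles(self, genome, i: int) -> tuple[str, str]:
        name = self.chrom_names[self.chrom_idx[i]]
        codes = genome.codes(name)
        p = int(self.pos[i])  # 1-based
        if self.kind[i] == SNV:
            return decode(codes[p - 1 : p]), "ACGT"[self.base[i]]
        anchor = decode(codes[p - 1 : p])
        b = "ACGT"[self.base[i]]
        if self.kind[i] == DEL:
            return anchor + b, anchor
        return anchor, anchor + b

    def iter_records(self, genome) -> Iterator[VariantRecord]:
        """Yield each variant as a :class:`VariantRecord` (needs the genome
        to reconstruct indel REF/ALT strings)."""
        for i in range(len(self)):
            ref, alt = self._alleles(genome, i)
            yield VariantRecord(self.chrom_names[self.chrom_idx[i]],
                                int(self.pos[i]), ref, alt,
                                validated=bool(self.validated[i]))

    def to_vcf(self, genome, path) -> None:
        """Write an uncompressed VCF 4.2 file (VLD INFO flag marks validated
        records)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=VLD,Number=0,Type=Flag,'
                     'Description="Validated variant">\n')
            for name in self.chrom_names:
                fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            table = self.sort()
            for i in range(len(table)):
                ref, alt = table._alleles(genome, i)
                info = "VLD" if table.validated[i] else "."
                fh.write(f"{table.chrom_names[table.chrom_idx[i]]}\t"
                         f"{int(table.pos[i])}\t.\t{ref}\t{alt}\t.\t.\t{info}\n")


@dataclass
class SpectrumTable:
    """Per-class counts of a classified variant set.

    ``counts`` is keyed by the closed set of class keys of the relevant
    pairing scheme; fractions are percentages of ``total_classified``.
    """

    counts: dict[str, int]
    rejections: Counter = field(default_factory=Counter)

    @property
    def total_classified(self) -> int:
        return sum(self.counts.values())

    def fraction_pct(self, key: str) -> float:
        total = self.total_classified
        if total == 0:
            return float("nan")
        return 100.0 * self.counts[key] / total
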