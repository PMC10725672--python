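"""Codon-position nucleotide composition of coding sequences.

For an in-frame CDS, every base carries a codon-position label 1, 2 or 3.
This module counts mono-, di- and tri-nucleotides by the position of their
first base, in two modes:

* ``strand_independent`` — each CDS is counted as stored, 5'->3' in its own
  coding orientation (composition of the message, regardless of which genomic
  strand carries it).
* ``strand_dependent`` — every minus-strand CDS is replaced by its reverse
  complement, projecting all CDSs onto the single reference (Watson) strand;
  position labels are re-assigned cyclically 1,2,3 from the 5' end of the
  reverse-complemented sequence.  Under this convention the position-1
  triplets of a minus-strand gene are exactly the reverse complements
  ("anticodons", in the same-strand sense) of its codons, which is what the
  codon<->anticodon parity comparison needs.

From the k=1 table, per-position A/T, G/C and purine/pyrimidine ratios are
derived; coding strands typically show a purine excess at codon position 1
(Szybalski's rule) compensated by pyrimidine bias at positions 2-3, so the
all-positions ratios return toward 1 — a local restoration of intrastrand
symmetry.
"""
from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from ._alphabet import encode
from .io import Genome, read_fasta
from .seqsym import percentage_difference, reverse_complement, round_half_up

__all__ = ["CdsRecord", "CdsLoadResult", "load_cds_set",
           "PositionCountTable", "position_kmer_counts", "ratio_table",
           "per_cds_ratios", "codon_anticodon_parity",
           "STRAND_INDEPENDENT", "STRAND_DEPENDENT"]

STRAND_INDEPENDENT = "strand_independent"
STRAND_DEPENDENT = "strand_dependent"


@dataclass(frozen=True)
class CdsRecord:
    """A spliced, in-frame coding sequence.

    ``sequence`` is stored 5'->3' in coding orientation; ``strand`` records
    which genomic strand carries the gene.  Length is a positive multiple
    of 3 and the sequence contains no N (violations are rejected at load
    time with a reason).
    """

    id: str
    strand: str
    sequence: str
    chrom: str | None = None
    exons: tuple[tuple[int, int], ...] | None = None  # 1-based inclusive

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3


@dataclass
class CdsLoadResult:
    records: list[CdsRecord]
    rejections: Counter = field(default_factory=Counter)


def _validate_cds(name: str, strand: str, seq: str,
                  rejections: Counter, **meta) -> CdsRecord | None:
    if len(seq) < 3 or len(seq) % 3:
        rejections["frame_error"] += 1
        return None
    if "N" in seq:
        rejections["contains_N"] += 1
        return None
    return CdsRecord(name, strand, seq, **meta)


_EXON_RE = re.compile(r"^(\d+)-(\d+)$")


def parse_cds_table(path) -> list[tuple[str, str, str, tuple[tuple[int, int], ...]]]:
    """Parse a CDS interval table: cds_id, chrom, strand, exon list
    ``start-end,start-end`` (1-based inclusive, genomic order)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"CDS table row needs 4 columns: {line!r}")
            cds_id, chrom, strand, exon_field = fields
            if strand not in "+-":
                raise ValueError(f"invalid strand {strand!r} for {cds_id}")
            exons = []
            for token in exon_field.split(","):
                m = _EXON_RE.match(token.strip())
                if not m:
                    raise ValueError(f"invalid exon {token!r} for {cds_id}")
                exons.append((int(m.group(1)), int(m.group(2))))
            rows.append((cds_id, chrom, strand, tuple(exons)))
    return rows


def load_cds_set(cds_fasta=None, genome: Genome | None = None,
                 cds_table=None,
                 exclude_name_pattern: str | None = None) -> CdsLoadResult:
    """Load and validate a CDS set.

    Either ``cds_fasta`` (records already spliced and in coding
    orientation; strand defaults to '+') or ``genome`` + ``cds_table``
    (exons extracted from the genome; minus-strand CDSs are the reverse
    complement of the concatenated exons).  ``exclude_name_pattern`` drops
    records whose id matches the regex (e.g. hypothetical-protein filters
    on bacterial annotation); off by default.
    """
    if (cds_fasta is None) == (genome is None or cds_table is None):
        raise ValueError("provide either cds_fasta or genome + cds_table")
    rejections: Counter = Counter()
    records: list[CdsRecord] = []
    name_re = re.compile(exclude_name_pattern) if exclude_name_pattern else None

    if cds_fasta is not None:
        for name, seq in read_fasta(cds_fasta).items():
            if name_re and name_re.search(name):
                rejections["name_excluded"] += 1
                continue
            rec = _validate_cds(name, "+", seq, rejections)
            if rec is not None:
                records.append(rec)
        return CdsLoadResult(records, rejections)

    for cds_id, chrom, strand, exons in parse_cds_table(cds_table):
        if name_re and name_re.search(cds_id):
            rejections["name_excluded"] += 1
            continue
        if chrom not in genome:
            rejections["coordinate_error"] += 1
            continue
        try:
            covered = []
            last_end = 0
            for start, end in exons:
                if start <= last_end:
                    raise ValueError("overlapping or unordered exons")
                covered.append(genome.seq(chrom, start, end))
                last_end = end
        except ValueError:
            rejections["coordinate_error"] += 1
            continue
        seq = "".join(covered)
        if strand == "-":
            seq = reverse_complement(seq)
        rec = _validate_cds(cds_id, strand, seq, rejections,
                            chrom=chrom, exons=exons)
        if rec is not None:
            records.append(rec)
    return CdsLoadResult(records, rejections)


@dataclass
class PositionCountTable:
    """k-mer counts stratified by codon position of the k-mer's first base.

    ``counts[kmer]`` is a length-3 array (positions 1..3); k-mers may cross
    codon boundaries, and k-mers overrunning a CDS 3' end are dropped (so
    only k=1 has no boundary loss).  ``total(kmer)`` sums the positions.
    """

    k: int
    mode: str
    counts: dict[str, np.ndarray]

    def total(self, kmer: str) -> int:
        return int(self.counts[kmer].sum())

    def position(self, kmer: str, position: int) -> int:
        return int(self.counts[kmer][position - 1])

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(kmer=kmer, P1=int(v[0]), P2=int(v[1]), P3=int(v[2]),
                     total=int(v.sum()))
                for kmer, v in sorted(self.counts.items())]
        return pd.DataFrame(rows)


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def position_kmer_counts(cds_set: Iterable[CdsRecord], k: int,
                         mode: str = STRAND_INDEPENDENT) -> PositionCountTable:
    """Count k-mers (k in 1..3) by codon position over a CDS set."""
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    if mode not in (STRAND_INDEPENDENT, STRAND_DEPENDENT):
        raise ValueError(f"unknown mode {mode!r}")
    acc = np.zeros((3, 4 ** k), dtype=np.int64)
    for rec in cds_set:
        seq = rec.sequence
        if mode == STRAND_DEPENDENT and rec.strand == "-":
            seq = reverse_complement(seq)
        codes = encode(seq).astype(np.int64)
        n = codes.size - k + 1
        kcodes = np.zeros(n, dtype=np.int64)
        for i in range(k):
            kcodes = kcodes * 4 + codes[i : i + n]
        for label in range(3):
            acc[label] += np.bincount(kcodes[label::3], minlength=4 ** k)
    counts = {_decode_kmer(c, k): acc[:, c].copy() for c in range(4 ** k)}
    return PositionCountTable(k, mode, counts)


def _ratios(a: int, c: int, g: int, t: int) -> dict:
    return dict(
        at_ratio=a / t if t else math.nan,
        gc_ratio=g / c if c else math.nan,
        pur_pyr_ratio=(a + g) / (c + t) if (c + t) else math.nan,
    )


def ratio_table(table: PositionCountTable) -> pd.DataFrame:
    """A/T, G/C and Pur/Pyr ratios per codon position plus the all-positions
    total (the 'four ratios': P1, P2, P3, total).  Requires a k=1 table."""
    if table.k != 1:
        raise ValueError("ratio_table requires a k=1 position count table")
    rows = []
    for position in (1, 2, 3):
        counts = {b: table.position(b, position) for b in "ACGT"}
        rows.append(dict(position=str(position), **counts,
                         **_ratios(counts["A"], counts["C"],
                                   counts["G"], counts["T"])))
    totals = {b: table.total(b) for b in "ACGT"}
    rows.append(dict(position="total", **totals,
                     **_ratios(totals["A"], totals["C"],
                               totals["G"], totals["T"])))
    return pd.DataFrame(rows)


def per_cds_ratios(cds_set: Iterable[CdsRecord],
                   mode: str = STRAND_INDEPENDENT) -> pd.DataFrame:
    """Per-CDS ratio rows (one CDS at a time), the per-gene analogue of
    :func:`ratio_table` used for scatter-style composition summaries."""
    frames = []
    for rec in cds_set:
        frame = ratio_table(position_kmer_counts([rec], 1, mode))
        frame.insert(0, "cds_id", rec.id)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["cds_id", "position", "A", "C", "G", "T",
                                     "at_ratio", "gc_ratio", "pur_pyr_ratio"])
    return pd.concat(frames, ignore_index=True)


def codon_anticodon_parity(table: PositionCountTable) -> pd.DataFrame:
    """Parity of codon vs reverse-complement-codon counts on the reference
    strand.

    Uses position-1 trinucleotide counts of a strand-dependent table: after
    projecting all CDSs onto the Watson strand, the position-1 triplet count
    of a codon c includes the anticodon contributions of minus-strand genes,
    and intrastrand symmetry predicts count(c) ~ count(rc(c)).  The 64
    codons form exactly 32 reverse-complement pairs (no triplet is its own
    reverse complement).
    """
    if table.k != 3:
        raise ValueError("codon/anticodon parity requires a k=3 table")
    if table.mode != STRAND_DEPENDENT:
        raise ValueError("codon/anticodon parity requires a strand_dependent "
                         "table")
    rows = []
    for codon in sorted(table.counts):
        anti = reverse_complement(codon)
        if codon > anti:
            continue
        a = table.position(codon, 1)
        b = table.position(anti, 1)
        raw = percentage_difference(a, b)
        rows.append(dict(codon=codon, anticodon=anti, count=a, rc_count=b,
                         diff_pct=(round_half_up(abs(raw))
                                   if not math.isnan(raw) else raw),
                         diff_pct_raw=raw))
    frame = pd.DataFrame(rows)
    frame.insert(0, "no", range(1, len(frame) + 1))
    return frame
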