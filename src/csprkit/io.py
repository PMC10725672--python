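"""Format I/O: FASTA genomes, VCF variant streams, and TSV reports.

Coordinate convention: all user-facing coordinates (VCF POS, CDS interval
tables) are 1-based inclusive; internal sequence access is 0-based half-open.
The conversion happens in exactly one place, :meth:`Genome.codes` callers
subtracting 1, so off-by-one bugs cannot multiply.
"""
from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterator

import numpy as np
from Bio import SeqIO

from ._version import __version__ as _version
from ._alphabet import DnaAlphabetError, decode, encode
from .variants import VariantRecord

log = logging.getLogger("csprkit")

__all__ = ["Genome", "read_fasta", "read_vcf", "ReportTable", "write_report"]


class Genome:
    """Named chromosome sequences with numeric random access.

    Wraps a dict of uint8 code arrays (A=0,C=1,G=2,T=3,N=4).  Built from a
    FASTA file or directly from strings/arrays (the simulator's path).
    """

    def __init__(self, chromosomes: dict[str, "np.ndarray | str"]):
        self._codes: dict[str, np.ndarray] = {}
        for name, seq in chromosomes.items():
            self._codes[name] = seq if isinstance(seq, np.ndarray) else encode(seq, name)

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        return cls(read_fasta(path))

    @property
    def names(self) -> list[str]:
        return list(self._codes)

    def __contains__(self, name: str) -> bool:
        return name in self._codes

    def length(self, name: str) -> int:
        return self._codes[name].size

    def codes(self, name: str) -> np.ndarray:
        return self._codes[name]

    def seq(self, name: str, start: int | None = None, end: int | None = None) -> str:
        """Sequence of ``name`` (optionally 1-based inclusive ``start..end``)."""
        codes = self._codes[name]
        if start is not None:
            if start < 1 or end is None or end > codes.size or end < start:
                raise ValueError(f"interval {start}-{end} out of bounds for "
                                 f"{name} (length {codes.size})")
            codes = codes[start - 1 : end]
        return decode(codes)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, codes in self._codes.items():
                fh.write(f">{name}\n")
                seq = decode(codes)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered name -> sequence dict.

    Names are the first whitespace-delimited token; sequences are validated
    over {A,C,G,T,N} (case-insensitive) and stored upper-case.  Duplicate
    names and invalid characters are errors naming the record and offset.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq)
        try:
            encode(seq, rec.id)
        except DnaAlphabetError:
            raise
        out[rec.id] = seq.upper()
    return out


def read_vcf(path, validated_flag: str = "VLD",
             strict: bool = False) -> Iterator[VariantRecord]:
    """Stream a VCF as :class:`VariantRecord`, splitting multi-allelic rows.

    Only CHROM, POS, REF, ALT, FILTER and the presence of the
    ``validated_flag`` INFO key are consumed.  Records with a non-positive
    POS or alleles outside {A,C,G,T} are malformed: skipped with a log line
    in lenient mode, fatal when ``strict``.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            filt = ";".join(rec.filter.keys()) or "."
            validated = validated_flag in rec.info
            alts = rec.alts or ()
            for alt in alts:
                record = VariantRecord(rec.chrom, rec.pos, rec.ref or "",
                                       alt or "", filt, validated)
                if (record.pos < 1 or not record.ref or not record.alt
                        or any(b not in "ACGT" for b in record.ref + record.alt)):
                    if strict:
                        raise ValueError(f"malformed VCF record at "
                                         f"{rec.chrom}:{rec.pos}")
                    log.warning("skipping malformed record %s:%s %s>%s",
                                rec.chrom, rec.pos, record.ref, record.alt)
                    continue
                yield record


# --------------------------------------------------------------------------
# Report serialization

#: columns rendered as 2-decimal percentages (half-up); NaN renders as NA
PERCENT_COLUMNS = {"diff_pct", "fraction_pct", "rc_fraction_pct",
                   "diff_pct_raw"}


@dataclass
class ReportTable:
    """A typed report with provenance, serialized as commented TSV.

    Numeric rendering rules (2-decimal percents, ``NA`` for undefined
    values) are applied only at serialization; the underlying frame keeps
    full precision.
    """

    kind: str
    frame: "object"  # pandas.DataFrame
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # label -> path

    def provenance_lines(self, no_timestamp: bool = False) -> list[str]:
        lines = [f"# csprkit {_version} report={self.kind}"]
        if not no_timestamp:
            stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
            lines.append(f"# created={stamp}")
        for key, value in self.params.items():
            lines.append(f"# param {key}={value}")
        for label, path in self.inputs.items():
            lines.append(f"# input {label}={path} sha256={_file_sha256(path)}")
        return lines


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _render(value, column: str) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        if column in PERCENT_COLUMNS:
            return f"{value:.2f}"
        return f"{value:.6g}"
    return str(value)


def write_report(table: ReportTable, path, no_timestamp: bool = False) -> None:
    """Write ``table`` as tab-separated text with leading ``#`` provenance."""
    frame = table.frame
    with open(path, "w") as fh:
        for line in table.provenance_lines(no_timestamp):
            fh.write(line + "\n")
        fh.write("\t".join(map(str, frame.columns)) + "\n")
        for row in frame.itertuples(index=False):
            fh.write("\t".join(_render(v, c) for v, c in
                               zip(row, frame.columns)) + "\n")


def read_report(path):
    """Round-trip reader for :func:`write_report` output (comments skipped)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
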