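"""Codon-position composition counting, ratios and codon/anticodon parity."""
import math

import numpy as np
import pytest

from csprkit import (STRAND_DEPENDENT, STRAND_INDEPENDENT, CdsRecord,
                     codon_anticodon_parity, load_cds_set,
                     position_kmer_counts, ratio_table, reverse_complement)
from csprkit.codon_composition import per_cds_ratios
from csprkit.io import Genome


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def test_load_cds_fasta_and_frame_validation(tmp_path):
    path = tmp_path / "cds.fa"
    write_fasta(path, {"ok": "ATGAAATAG", "short": "ATGAAATA",
                       "withn": "ATGANATAG"})
    result = load_cds_set(cds_fasta=path)
    assert [r.id for r in result.records] == ["ok"]
    assert result.records[0].strand == "+"
    assert result.rejections["frame_error"] == 1
    assert result.rejections["contains_N"] == 1


def test_load_cds_from_genome_table_minus_strand(tmp_path):
    genome = Genome({"chr1": "CTATTTCAT"})
    table = tmp_path / "cds.tsv"
    table.write_text("gene1\tchr1\t-\t1-9\n")
    result = load_cds_set(genome=genome, cds_table=table)
    (rec,) = result.records
    assert rec.sequence == "ATGAAATAG"
    assert rec.strand == "-"


def test_load_cds_coordinate_errors(tmp_path):
    genome = Genome({"chr1": "CTATTTCAT"})
    table = tmp_path / "cds.tsv"
    table.write_text("over\tchr1\t+\t1-12\n"
                     "overlap\tchr1\t+\t1-6,4-9\n"
                     "badchrom\tchr9\t+\t1-9\n")
    result = load_cds_set(genome=genome, cds_table=table)
    assert not result.records
    assert result.rejections["coordinate_error"] == 3


def test_position_counts_hand_example_k1():
    rec = CdsRecord("g", "+", "ATGAAATAG")
    table = position_kmer_counts([rec], 1, STRAND_INDEPENDENT)
    assert table.position("A", 1) == 2 and table.position("T", 1) == 1
    assert table.position("A", 2) == 2 and table.position("T", 2) == 1
    assert table.position("G", 3) == 2 and table.position("A", 3) == 1
    # k=1 has no boundary loss: position sums = total base count
    assert sum(table.total(b) for b in "ACGT") == 9


def test_position_counts_k3_p1_is_codon_multiset():
    rec = CdsRecord("g", "+", "ATGAAATAG")
    table = position_kmer_counts([rec], 3, STRAND_INDEPENDENT)
    codons = {k: int(v[0]) for k, v in table.counts.items() if v[0]}
    assert codons == {"ATG": 1, "AAA": 1, "TAG": 1}
    # sum of P1 counts over all triplets = total codon count
    assert sum(v[0] for v in table.counts.values()) == rec.n_codons


def test_total_is_sum_of_positions():
    rec = CdsRecord("g", "+", "ATGAAACCCGGGTAG")
    for k in (1, 2, 3):
        table = position_kmer_counts([rec], k, STRAND_INDEPENDENT)
        for kmer, v in table.counts.items():
            assert table.total(kmer) == v.sum()


def test_strand_dependent_equals_plus_strand_reverse_complement():
    minus = CdsRecord("g", "-", "ATGAAATAG")
    plus = CdsRecord("g", "+", reverse_complement("ATGAAATAG"))
    for k in (1, 2, 3):
        a = position_kmer_counts([minus], k, STRAND_DEPENDENT)
        b = position_kmer_counts([plus], k, STRAND_INDEPENDENT)
        assert {m: tuple(v) for m, v in a.counts.items()} == \
               {m: tuple(v) for m, v in b.counts.items()}


def test_plus_only_set_mode_invariance():
    recs = [CdsRecord("a", "+", "ATGAAATAG"),
            CdsRecord("b", "+", "CCCGGGATGTTT")]
    for k in (1, 2, 3):
        a = position_kmer_counts(recs, k, STRAND_INDEPENDENT)
        b = position_kmer_counts(recs, k, STRAND_DEPENDENT)
        assert all((a.counts[m] == b.counts[m]).all() for m in a.counts)


def test_ratio_table_examples():
    rec = CdsRecord("g", "+", "ATGAAATAG")
    frame = ratio_table(position_kmer_counts([rec], 1, STRAND_INDEPENDENT))
    p1 = frame[frame.position == "1"].iloc[0]
    assert p1.at_ratio == 2.0
    total = frame[frame.position == "total"].iloc[0]
    # A=5 T=2 G=2 C=0: gc_ratio undefined on zero denominator
    assert math.isnan(total.gc_ratio)
    assert total.at_ratio == 2.5
    balanced = CdsRecord("g", "+", "ACGTCATGC")  # no equal-split per position
    frame2 = ratio_table(position_kmer_counts([balanced], 1,
                                              STRAND_INDEPENDENT))
    tot = frame2[frame2.position == "total"].iloc[0]
    assert tot.pur_pyr_ratio == pytest.approx((2 + 2) / (3 + 2))


def test_ratio_table_requires_k1():
    rec = CdsRecord("g", "+", "ATGAAATAG")
    with pytest.raises(ValueError):
        ratio_table(position_kmer_counts([rec], 2, STRAND_INDEPENDENT))


def test_per_cds_ratios_one_block_per_record():
    recs = [CdsRecord("a", "+", "ATGAAATAG"), CdsRecord("b", "+", "CCCGGG")]
    frame = per_cds_ratios(recs)
    assert set(frame.cds_id) == {"a", "b"}
    assert len(frame) == 8  # 4 rows per CDS


def test_codon_anticodon_parity_single_gene():
    rec = CdsRecord("g", "+", "ATGTAG")
    table = position_kmer_counts([rec], 3, STRAND_DEPENDENT)
    frame = codon_anticodon_parity(table)
    assert len(frame) == 32  # 64 codons form exactly 32 rc pairs
    row = frame[(frame.codon == "ATG") | (frame.anticodon == "ATG")].iloc[0]
    assert {row["count"], row.rc_count} == {1, 0}
    assert row.diff_pct == 200.0


def test_codon_anticodon_parity_exact_on_twin_set():
    seq = "ATGCCCAAATTTGGGTAG"
    recs = [CdsRecord("a", "+", seq), CdsRecord("a_twin", "-", seq)]
    table = position_kmer_counts(recs, 3, STRAND_DEPENDENT)
    frame = codon_anticodon_parity(table)
    assert (frame.diff_pct.fillna(0) == 0).all()
    assert frame["count"].sum() + frame.rc_count.sum() == 2 * len(seq) // 3


def test_codon_anticodon_parity_mode_guard():
    rec = CdsRecord("g", "+", "ATGTAG")
    with pytest.raises(ValueError):
        codon_anticodon_parity(position_kmer_counts([rec], 3,
                                                    STRAND_INDEPENDENT))
    with pytest.raises(ValueError):
        codon_anticodon_parity(position_kmer_counts([rec], 2,
                                                    STRAND_DEPENDENT))
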