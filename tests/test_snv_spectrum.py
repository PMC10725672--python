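"""Contextual SNV classification scheme, tabulation and parity reporting."""
import itertools
import math

import pytest

from csprkit import (ContextClass, FilterConfig, Rejection, VariantRecord,
                     parity_report, reverse_complement, tabulate_snv_spectrum)
from csprkit.io import Genome
from csprkit.snv_spectrum import (classify_snv, default_scheme,
                                  enumerate_scheme, rc_undirected,
                                  undirected_key)
from csprkit.variants import SpectrumTable


def brute_force_scheme():
    """Independent enumeration oracle over all (left, ref, alt, right)."""
    undirected = set()
    for left, ref, alt, right in itertools.product("ACGT", repeat=4):
        if ref == alt:
            continue
        t1, t2 = left + ref + right, left + alt + right
        undirected.add(tuple(sorted((t1, t2))))
    comp = str.maketrans("ACGT", "TGCA")

    def rc(t):
        return t.translate(comp)[::-1]

    fixed = {c for c in undirected
             if tuple(sorted((rc(c[0]), rc(c[1])))) == c}
    return undirected, fixed


def test_scheme_cardinalities_match_brute_force():
    scheme = enumerate_scheme()
    undirected, fixed = brute_force_scheme()
    assert scheme.n_directed == 192
    assert len(scheme.undirected_classes) == len(undirected) == 96
    assert len(scheme.self_complementary) == len(fixed) == 8
    assert len(scheme.comparison_pairs) == 44
    assert 2 * len(scheme.comparison_pairs) + len(scheme.self_complementary) == 96
    assert set(scheme.self_complementary) == {undirected_key(*c) for c in fixed}


def test_scheme_pairs_agree_with_named_examples():
    scheme = enumerate_scheme()
    pairs = {frozenset(p) for p in scheme.comparison_pairs}
    assert frozenset({undirected_key("AGC", "ATC"),
                      undirected_key("GCT", "GAT")}) in pairs
    assert undirected_key("AGT", "ACT") in scheme.self_complementary
    assert undirected_key("CAG", "CTG") in scheme.self_complementary


def test_rc_map_is_involution_with_exactly_eight_fixed_points():
    scheme = enumerate_scheme()
    fixed = []
    for key in scheme.undirected_classes:
        assert rc_undirected(rc_undirected(key)) == key
        if rc_undirected(key) == key:
            fixed.append(key)
    assert len(fixed) == 8
    # fixed points are exactly: right = complement(left), alt = complement(ref)
    for key in fixed:
        t1, t2 = key.split("<->")
        assert t1 == reverse_complement(t2)


def test_self_complementary_middle_bases_are_complementary():
    for key in enumerate_scheme().self_complementary:
        t1, t2 = key.split("<->")
        assert t2[1] == reverse_complement(t1[1])


def test_pyrimidine_oriented_pairs_partition():
    scheme = enumerate_scheme()
    assert len(scheme.pyrimidine_oriented_pairs) == 16
    for pyr, pur in scheme.pyrimidine_oriented_pairs:
        a, b = pyr.split("<->")
        assert {a[1], b[1]} <= set("CT")
        c, d = pur.split("<->")
        assert {c[1], d[1]} <= set("AG")


def test_classify_snv_examples(tiny_genome):
    variant = VariantRecord("chr1", 3, "G", "T")
    assert classify_snv(variant, tiny_genome) == undirected_key("AGC", "ATC")
    assert classify_snv(VariantRecord("chr1", 1, "T", "A"),
                        tiny_genome) == Rejection.edge_of_sequence
    n_genome = Genome({"chr1": "TANCT"})
    assert classify_snv(VariantRecord("chr1", 3, "N", "T"),
                        n_genome) == Rejection.context_contains_n
    flank_n = Genome({"chr1": "TNGCT"})
    assert classify_snv(VariantRecord("chr1", 3, "G", "T"),
                        flank_n) == Rejection.context_contains_n


def test_classify_snv_filter_rejections(tiny_genome):
    assert classify_snv(VariantRecord("chrX", 3, "G", "T"),
                        tiny_genome) == Rejection.chromosome_excluded
    assert classify_snv(VariantRecord("chr9", 3, "G", "T"),
                        tiny_genome) == Rejection.chromosome_unknown
    assert classify_snv(VariantRecord("chr1", 3, "G", "T", filter="q10"),
                        tiny_genome) == Rejection.filter_failed
    filters = FilterConfig(require_validated=True)
    assert classify_snv(VariantRecord("chr1", 3, "G", "T", validated=False),
                        tiny_genome, filters) == Rejection.not_validated
    assert classify_snv(VariantRecord("chr1", 3, "A", "T"),
                        tiny_genome) == Rejection.reference_mismatch
    assert classify_snv(VariantRecord("chr1", 3, "GA", "T"),
                        tiny_genome) == Rejection.not_snv


def test_classify_snv_strict_mode_raises_on_mismatch(tiny_genome):
    from csprkit.variants import ReferenceMismatchError

    with pytest.raises(ReferenceMismatchError):
        classify_snv(VariantRecord("chr1", 3, "A", "T"), tiny_genome,
                     FilterConfig(strict=True))


def test_tabulate_empty_stream(tiny_genome):
    spectrum = tabulate_snv_spectrum(iter([]), tiny_genome)
    assert spectrum.total_classified == 0
    assert all(v == 0 for v in spectrum.counts.values())
    assert math.isnan(spectrum.fraction_pct(next(iter(spectrum.counts))))


def test_tabulate_single_variant_and_duplicates(tiny_genome):
    variants = [VariantRecord("chr1", 3, "G", "T")] * 3
    spectrum = tabulate_snv_spectrum(iter(variants), tiny_genome)
    key = undirected_key("AGC", "ATC")
    assert spectrum.counts[key] == 1
    assert spectrum.fraction_pct(key) == 100.0
    assert spectrum.rejections[Rejection.duplicate] == 2
    assert (spectrum.total_classified
            + sum(spectrum.rejections.values()) == len(variants))


def test_parity_report_structure_and_arithmetic():
    scheme = default_scheme()
    counts = {k: 0 for k in scheme.undirected_classes}
    key, rc_key = scheme.comparison_pairs[0]
    counts[key], counts[rc_key] = 312720, 310244
    report = parity_report(SpectrumTable(counts), scheme)
    assert len(report) == 52  # 44 pair rows + 8 self-complementary rows
    assert report.self_complementary.sum() == 8
    row = report[report["count"] == 312720].iloc[0]
    assert row.diff_pct == 0.79
    equal = report[(report.rc_count == 0) & (report["count"] == 0)
                   & ~report.self_complementary]
    assert equal.diff_pct.isna().all()


def test_parity_report_requires_closed_scheme():
    scheme = default_scheme()
    with pytest.raises(KeyError):
        parity_report(SpectrumTable({"bogus": 1}), scheme)


def test_context_class_validation():
    with pytest.raises(ValueError):
        ContextClass("A", "G", "G", "C")
    with pytest.raises(ValueError):
        ContextClass("A", "G", "B", "C")
    assert ContextClass("A", "G", "T", "C").directed_key == "AGC>ATC"
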