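"""Generators: determinism, construction guarantees, parameter recovery."""
import math

import numpy as np
import pytest

from csprkit import (STRAND_DEPENDENT, STRAND_INDEPENDENT, FilterConfig,
                     Rejection, estimate_strand_bias, kmer_parity_table,
                     parity_report, position_kmer_counts, simulate_cds_set,
                     simulate_genome, simulate_variants,
                     tabulate_indel_spectrum, tabulate_snv_spectrum,
                     codon_anticodon_parity)
from csprkit.synthetic_data import (CdsSimulationConfig, SimulationConfig,
                                    position_weighted_codon_table)


def small_config(**kwargs):
    defaults = dict(seed=1, chromosomes=(("chr1", 50_000),))
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def test_genome_determinism_and_lengths(tmp_path):
    config = small_config(chromosomes=(("chr1", 10_000), ("chr2", 4_000)))
    g1 = simulate_genome(config)
    g2 = simulate_genome(config)
    assert g1.names == ["chr1", "chr2"]
    assert g1.length("chr1") == 10_000 and g1.length("chr2") == 4_000
    p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
    g1.to_fasta(p1)
    g2.to_fasta(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_variant_set_determinism(tmp_path):
    config = small_config(n_snvs=500, n_indels=100)
    genome = simulate_genome(config)
    v1 = simulate_variants(genome, config)
    v2 = simulate_variants(genome, config)
    p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
    v1.to_vcf(genome, p1)
    v2.to_vcf(genome, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_perfect_cspr_genome_has_exact_kmer_parity():
    config = small_config(genome_mode="perfect_cspr",
                          chromosomes=(("chr1", 20_000),))
    genome = simulate_genome(config)
    seq = genome.seq("chr1")
    for k in (1, 2, 3):
        for row in kmer_parity_table(seq, k):
            assert row.count_fwd == row.count_rc


def test_perfect_cspr_needs_even_length():
    with pytest.raises(ValueError):
        simulate_genome(small_config(genome_mode="perfect_cspr",
                                     chromosomes=(("chr1", 11),)))


def test_simulated_variants_are_reference_consistent():
    config = small_config(n_snvs=2_000, n_indels=500)
    genome = simulate_genome(config)
    table = simulate_variants(genome, config)
    spectrum = tabulate_snv_spectrum(table.iter_records(genome), genome)
    indels = tabulate_indel_spectrum(table.iter_records(genome), genome)
    assert spectrum.rejections[Rejection.reference_mismatch] == 0
    assert indels.spectrum.rejections[Rejection.reference_mismatch] == 0
    assert spectrum.total_classified == 2_000
    assert indels.spectrum.total_classified == 500


def test_requesting_more_snvs_than_sites_fails():
    config = small_config(chromosomes=(("chr1", 100),), n_snvs=200)
    genome = simulate_genome(config)
    with pytest.raises(ValueError):
        simulate_variants(genome, config)


def test_validated_fraction_and_filter_path():
    config = small_config(chromosomes=(("chr1", 30_000), ("chrX", 10_000)),
                          n_snvs=3_000, validated_fraction=0.5)
    genome = simulate_genome(config)
    table = simulate_variants(genome, config)
    filters = FilterConfig(require_validated=True)
    spectrum = tabulate_snv_spectrum(table, genome, filters)
    assert spectrum.rejections[Rejection.chromosome_excluded] > 0
    assert spectrum.rejections[Rejection.not_validated] > 0
    total = spectrum.total_classified + sum(spectrum.rejections.values())
    assert total == len(table)


def test_beta_zero_signed_diffs_center_on_zero():
    config = small_config(chromosomes=(("chr1", 2_000_000),), n_snvs=200_000)
    genome = simulate_genome(config)
    spectrum = tabulate_snv_spectrum(simulate_variants(genome, config), genome)
    report = parity_report(spectrum)
    signed = report.loc[~report.self_complementary, "diff_pct_raw"]
    # each pair diff has sd ~ 200/sqrt(S); the mean of 44 pairs ~ sd/sqrt(44)
    pair_sd = 200.0 / math.sqrt(2 * 200_000 / 96)
    assert abs(signed.mean()) < 3 * pair_sd / math.sqrt(len(signed))


@pytest.mark.parametrize("beta,seed,tol", [
    (0.0, 1, 0.02),
    (0.2, 7, 0.02),   # recovery within +/-0.02 at n=1e5
])
def test_strand_bias_recovery(beta, seed, tol):
    config = SimulationConfig(seed=seed, chromosomes=(("chr1", 2_000_000),),
                              n_snvs=100_000, strand_bias=beta)
    genome = simulate_genome(config)
    spectrum = tabulate_snv_spectrum(simulate_variants(genome, config), genome)
    assert abs(estimate_strand_bias(spectrum) - beta) <= tol


def test_symmetric_indel_process_alignable_pair_parity():
    # per-pair noise is 200/sqrt(S) ~ 0.8% at S ~ 62,500; 3% is a wide
    # envelope (~3.75 sd) for the max over the 18 alignable pairs
    config = SimulationConfig(seed=2, chromosomes=(("chr1", 8_000_000),),
                              n_indels=2_000_000)
    genome = simulate_genome(config)
    result = tabulate_indel_spectrum(simulate_variants(genome, config),
                                     genome)
    assert result.spectrum.total_classified == 2_000_000
    alignable = result.parity[result.parity.alignable]
    assert len(alignable) == 18
    assert alignable.diff_pct.max() < 3.0


def test_strong_bias_pushes_pooled_parity_past_threshold():
    config = SimulationConfig(seed=3, chromosomes=(("chr1", 2_000_000),),
                              n_snvs=100_000, strand_bias=0.5)
    genome = simulate_genome(config)
    spectrum = tabulate_snv_spectrum(simulate_variants(genome, config), genome)
    assert estimate_strand_bias(spectrum) > 0.4


def test_estimator_boundaries():
    from csprkit.snv_spectrum import default_scheme
    from csprkit.variants import SpectrumTable

    scheme = default_scheme()
    counts = {k: 0 for k in scheme.undirected_classes}
    assert math.isnan(estimate_strand_bias(SpectrumTable(dict(counts))))
    for pyr, pur in scheme.pyrimidine_oriented_pairs:
        counts[pyr] = 10
    assert estimate_strand_bias(SpectrumTable(dict(counts))) == 1.0
    for pyr, pur in scheme.pyrimidine_oriented_pairs:
        counts[pur] = 10
    assert estimate_strand_bias(SpectrumTable(dict(counts))) == 0.0


def test_twelve_rate_expert_mode_breaks_parity():
    rates = {f"{r}>{a}": 1.0 for r in "ACGT" for a in "ACGT" if r != a}
    rates["C>T"] = 8.0  # not matched by G>A: directed asymmetry
    config = small_config(chromosomes=(("chr1", 1_000_000),), n_snvs=50_000,
                          directed_rates=rates)
    genome = simulate_genome(config)
    spectrum = tabulate_snv_spectrum(simulate_variants(genome, config), genome)
    assert estimate_strand_bias(spectrum) > 0.3


def test_cds_twin_mode_gives_exact_codon_anticodon_parity():
    config = small_config(chromosomes=(("chrA", 200_000),),
                          cds=CdsSimulationConfig(n_genes=60, twin_mode=True))
    sim = simulate_cds_set(config)
    assert len(sim.records) == 120
    table = position_kmer_counts(sim.records, 3, STRAND_DEPENDENT)
    frame = codon_anticodon_parity(table)
    assert (frame.diff_pct.fillna(0) == 0).all()


def test_cds_plus_only_strand_modes_agree():
    config = small_config(chromosomes=(("chrA", 200_000),),
                          cds=CdsSimulationConfig(n_genes=40,
                                                  minus_fraction=0.0))
    sim = simulate_cds_set(config)
    for k in (1, 2, 3):
        a = position_kmer_counts(sim.records, k, STRAND_INDEPENDENT)
        b = position_kmer_counts(sim.records, k, STRAND_DEPENDENT)
        assert all((a.counts[m] == b.counts[m]).all() for m in a.counts)


def test_cds_roundtrip_through_genome_and_table(tmp_path):
    config = small_config(chromosomes=(("chrA", 150_000),),
                          cds=CdsSimulationConfig(n_genes=50))
    sim = simulate_cds_set(config)
    from csprkit import Genome, load_cds_set

    fasta, table = tmp_path / "g.fa", tmp_path / "cds.tsv"
    sim.genome.to_fasta(fasta)
    sim.write_table(table)
    loaded = load_cds_set(genome=Genome.from_fasta(fasta), cds_table=table)
    assert len(loaded.records) == len(sim.records)
    for ours, theirs in zip(sim.records, loaded.records):
        assert ours.sequence == theirs.sequence
        assert ours.strand == theirs.strand


def test_cds_placement_error_when_genes_do_not_fit():
    config = small_config(chromosomes=(("chrA", 1_000),),
                          cds=CdsSimulationConfig(n_genes=50))
    with pytest.raises(ValueError):
        simulate_cds_set(config)


def test_purine_enriched_position1_ratio():
    # position-1 base distribution with purine fraction 0.6 -> Pur/Pyr 1.5
    weights = position_weighted_codon_table(
        [0.3, 0.2, 0.3, 0.2], [0.25] * 4, [0.25] * 4, exclude_stops=False)
    config = small_config(
        chromosomes=(("chrA", 2_000_000),),
        cds=CdsSimulationConfig(n_genes=300, gene_length=999,
                                codon_weights=weights))
    sim = simulate_cds_set(config)
    from csprkit import ratio_table

    frame = ratio_table(position_kmer_counts(sim.records, 1,
                                             STRAND_INDEPENDENT))
    p1 = frame[frame.position == "1"].iloc[0]
    n = 300 * 333  # position-1 bases drawn
    # sd of the ratio via delta method on a binomial purine fraction
    sd = math.sqrt(0.6 * 0.4 / n) / 0.4**2
    assert abs(p1.pur_pyr_ratio - 1.5) < 3 * sd


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(base_frequencies=(0.5, 0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        SimulationConfig(strand_bias=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(substitution_rates={t: 0.0 for t in
                                             ("C>A", "C>G", "C>T",
                                              "T>A", "T>C", "T>G")})


def test_config_file_roundtrip(tmp_path):
    path = tmp_path / "sim.cfg"
    path.write_text(
        "seed = 5\n"
        "chromosomes = chr1:1000, chr2:500\n"
        "base_frequencies = 0.3,0.2,0.2,0.3\n"
        "genome_mode = iid\n"
        "n_snvs = 10\n"
        "strand_bias = 0.1\n"
        "rate.C>T = 2.0\n"
        "cds.n_genes = 7\n"
        "cds.twin_mode = true\n")
    config = SimulationConfig.from_file(path)
    assert config.seed == 5
    assert config.chromosomes == (("chr1", 1000), ("chr2", 500))
    assert config.substitution_rates["C>T"] == 2.0
    assert config.cds.n_genes == 7 and config.cds.twin_mode is True
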