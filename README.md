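# csprkit

Analysis toolkit for **intrastrand DNA symmetry** — Chargaff's second parity
rule (CSPR): within a single, sufficiently long DNA strand, the count of any
oligonucleotide is nearly equal to the count of its reverse complement
(for mononucleotides, G ≈ C and A ≈ T).  `csprkit` is aimed at genome and
population-genetics analysts who want to quantify how closely genomes,
variant sets and coding sequences comply with this symmetry, and at method
developers who need a fully seeded synthetic test bed for such analyses.

## What it computes

**Contextual SNV parity.**  A substitution X→Y with forward-strand flanks N
defines a directed class NXN>NYN; there are 4·4·3·4 = 192 of them, folded by
ref/alt interchange into 96 undirected classes {NXN↔NYN}.  Reverse
complementation pairs these into **44 comparison pairs** plus **8
self-complementary classes** (right flank = complement of left, alt =
complement of ref).  For each pair with counts A and B the report shows the
percentage difference

    d = 200 · (A − B) / (A + B),

rendered as |d| rounded half-up to two decimals.  Population-scale variant
sets sit in a sub-1% parity regime for every pair; no COSMIC-style
pyrimidine folding is applied, because collapsing C>T with G>A would erase
exactly the parity being measured.

**Single-base indel parity.**  An indel of base B between flanks L and R
defines one of 64 classes L-R↔LBR, forming 32 reverse-complement pairs, of
which **18 are alignable** (B differs from both flanks) and **14 ambiguous**
(homopolymer-adjacent; gap placement not unique, so counts are reported but
not compared).

**Codon-position composition.**  Mono-/di-/tri-nucleotide counts of a CDS
set stratified by codon position, strand-independent or projected onto the
reference strand (minus-strand CDSs reverse-complemented, positions
relabelled 1,2,3 from the new 5′ end), with per-position A/T, G/C and
Pur/Pyr ratios and the 32-pair codon↔anticodon parity table.  Coding strands
typically show a purine excess at position 1 (Szybalski's rule) compensated
at positions 2–3.

**Genetic-code graph.**  Joining the amino acids encoded by each of the 32
codon/reverse-complement codon pairs (stop codons as three separate nodes)
splits the standard code into three components — 8, 5 and 7 amino acids
carrying 1, 2 and 0 stop codons — each containing aromatic, basic, polar and
nonpolar residues.

**Exact combinatorics.**  The number of length-N sequences with #A = #T and
#G = #C is (C(N, N/2))² ≈ 4ᴺ·2/(πN) for even N (0 for odd N); the
normalized ratio count·N/4ᴺ increases monotonically to 2/π ≈ 0.6366.

**Synthetic data.**  Seeded generators for genomes (iid or exactly
symmetric s + rc(s)), variant sets under a six-rate pyrimidine-anchored
substitution model with a strand-bias scalar β (β = 0 is the no-strand-bias
regime; a 12-rate expert mode breaks parity arbitrarily), and CDS sets with
configurable codon frequencies, strand assignment and an exact
reverse-complement twin mode — plus the pooled estimator `estimate_strand_bias`
that recovers β from a spectrum.

## Worked example

```python
from csprkit import (estimate_strand_bias, parity_report, simulate_genome,
                     simulate_variants, tabulate_snv_spectrum)
from csprkit.synthetic_data import SimulationConfig

config = SimulationConfig(seed=1, chromosomes=(("chr1", 2_000_000),),
                          n_snvs=200_000, strand_bias=0.0)
genome = simulate_genome(config)
spectrum = tabulate_snv_spectrum(simulate_variants(genome, config), genome)
report = parity_report(spectrum, sort=True)
print(report[~report.self_complementary].diff_pct.mean())
print(estimate_strand_bias(spectrum))
```

prints (seed 1):

```
2.0745454545454542
0.0021977360308285164
```

i.e. with 200,000 strand-symmetric variants the 44 reverse-complement pairs
differ by ~2% on average — pure binomial noise, ~200/√(pair total) — and the
pooled strand-bias estimate is ≈ 0.002, consistent with the true β = 0.
Scaling to 3×10⁷ variants (see `tests/test_acceptance.py`) pushes every pair
below 1%, the parity regime observed in population variant databases.  The
scripts in `examples/` walk through each capability and print annotated
output; the `csprkit` CLI (`parity`, `snv-spectrum`, `indel-spectrum`,
`codon-comp`, `code-graph`, `count-symmetric`, `simulate`) exposes the same
operations on FASTA/VCF/TSV files.

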