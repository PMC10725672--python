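# Methods

This note documents the models, conventions and numerical choices behind
`csprkit`, and what the synthetic-data generators do and do not emulate.

## Parity statistics

All pairwise comparisons use the percentage difference
`d = 200·(A − B)/(A + B)`, signed and kept at full precision internally;
reports render `|d|` rounded **half-up** to two decimals and `NA` when
`A + B = 0`.  `d` is antisymmetric and bounded in [−200, 200].  For a pair
whose total `S = A + B` is split binomially with p = 1/2 (the
strand-symmetric null), `sd(d) ≈ 200/√S`; this is the yardstick used
throughout the tests to decide what "near-exact parity" means at a given
sample size.

## Contextual SNV classes

A substitution is read from the forward (top) strand of the reference with
its immediate flanks: 4·4·3·4 = 192 directed classes NXN>NYN, folded by
ref/alt interchange into 96 undirected classes.  Reverse complementation is
an involution on the undirected classes; its fixed points are exactly the 8
classes with right flank = complement(left flank) and alt = complement(ref),
leaving 44 comparison pairs.  The 88 classes participating in pairs and the
44 comparisons are both genuine descriptions of the same structure; the
implementation exposes the 44 + 8 form.  No pyrimidine-anchored (COSMIC-96)
folding is applied: adding C>T to G>A counts would remove precisely the
strand parity under study.

Record handling: multi-allelic VCF rows are split before classification;
deduplication is on (chrom, pos, ref, alt) with the first occurrence
winning; sex chromosomes {X, Y, chrX, chrY} are excluded by default;
`FILTER` must be `PASS` or `.`; the validation flag (INFO key `VLD`) is
enforced only with `require_validated`, since that annotation is
database-specific.  Every input record increments exactly one class or one
machine-readable rejection tally (accepted + rejections = input count).
Coordinates are 1-based in all user-facing formats and 0-based half-open
internally, converted in a single accessor.

Two classification routes exist — a per-record classifier for VCF streams
and a vectorized columnar route for simulator output — and the tests assert
they produce identical counts *and* identical rejection tallies; the
rejection precedence is chromosome → filter/validation → record shape →
sequence context.

## Indel classes

Only length-1, anchor-consistent indels are classified (REF/ALT lengths 2/1
or 1/2 sharing their first base); everything else is tallied
`not_single_base_indel` or `malformed_indel`.  The class of a deletion of B
with reference neighbours L and R, and of an insertion of B between L and
R, is the same L-R↔LBR; insertions and deletions are pooled per class with
separate sub-counts retained.  Indels are used exactly as given (no
re-left-alignment): an event whose base equals a flank is in a homopolymer
context where the gap position is not unique, which is why the 14 ambiguous
pairs are reported without a difference statistic.  Alignability is
invariant under reverse complementation, so the 18/14 split is a property
of pairs, not members.

## Codon-position composition

k-mers (k = 1, 2, 3) are counted at the codon position of their first base;
k-mers crossing codon boundaries count, k-mers overrunning the CDS 3′ end
are dropped (so only k = 1 is lossless).  In strand-dependent mode each
minus-strand CDS is replaced by its reverse complement and positions are
relabelled cyclically 1,2,3 from the new 5′ end.  Under this convention the
position-1 triplets of a minus-strand gene are exactly the same-strand
reverse complements of its codons, which makes the codon↔anticodon
comparison well-posed; the alternative convention (inheriting the original
labels, i.e. cycling 3,2,1) was rejected because it breaks that
correspondence.  The 64 codons form exactly 32 reverse-complement pairs —
a fixed point would need a self-complementary middle base, which does not
exist.

CDS records must be in frame (length a positive multiple of 3) and N-free;
violations are rejected with reasons.  Both pooled (per-set) and per-CDS
ratio outputs are provided, mirroring accumulative versus per-gene
analyses.  An optional name-pattern filter supports excluding
hypothetical-protein annotations in bacterial inputs; it is off by default
for synthetic data.

## Genetic-code graph

Stop codons are three distinct nodes; merging them would spuriously connect
the 8-amino-acid and 5-amino-acid components through a shared stop node.
The graph is a multigraph so that all 32 codon-pair edges are preserved even
where two pairs join the same amino acids.  Component shape labels
(pentagram/triangle/rhombus for 8/5/7 amino acids) follow the conventional
drawn geometry and are annotations only — no geometric claim is checked.
The chemical classification used for coverage is: aromatic {F,W,Y,H},
basic {K,R,H}, polar {S,T,N,Q,C,Y,D,E}, nonpolar {A,V,L,I,P,M,G,F,W}
(overlaps allowed); any standard scheme gives the same coverage result, and
the scheme used is printed in the report header.

## Combinatorics

Counts use arbitrary-precision integers; ratios switch to a log-gamma path
above n = 1000 to avoid overflow.  The true asymptotic of (C(N,N/2))² is
4ᴺ·2/(πN); the coarser normalization 4ᴺ/N omits the constant 2/π, so the
package reports the ratio count·N/4ᴺ together with its limit 2/π.  The
brute-force enumerator is capped at n ≤ 10 (4¹⁰ ≈ 10⁶ sequences) and serves
purely as an independent oracle for the closed form.

## Synthetic-data generators

**Genomes.**  `iid` draws bases independently from `base_frequencies`
(uniform by default, the composition under which context frequencies are
symmetric in expectation); `perfect_cspr` emits s + rc(s) per chromosome,
a sequence equal to its own reverse complement, hence *exactly* zero k-mer
parity deviation for every k — the construction oracle used by the parity
tests.

**Variants.**  Six pyrimidine-anchored rates r_t plus one scalar β ∈ [−1,1]:
a pyrimidine-site substitution of type t has rate r_t(1+β), the
reverse-complement type at a purine site r_t(1−β).  One scalar (rather than
12 free rates) makes the symmetric case β = 0 and the recovery problem
well-posed; `directed_rates` exposes the 12-rate mode for arbitrary parity
violations.  Sites are sampled *without replacement* with inclusion
probability proportional to the site's total rate, via exponential-race
keys (equivalent to successive weighted draws), so no site is mutated
twice; the alt allele is then drawn from the directed rates at that base.
Indel sites/bases are weighted by the same (1±β) factor on the
deleted/inserted base.  Deletions and insertions split binomially.  All
outputs are REF-consistent with the generating genome (round-trip checked:
zero `reference_mismatch` rejections) and byte-deterministic per seed.

**CDS sets.**  Genes are iid codon draws from a configurable weight table —
uniform over the 61 sense codons by default, with *no* enforced ATG/stop
bookends, an idealization that makes configured per-position base
compositions exact in expectation (with stop codons excluded, the realized
position-1 composition shifts slightly because all three stop codons start
with T; the composition-calibration test therefore uses a weight table with
stops included).  Genes are placed non-overlapping with iid spacers;
minus-strand genes are embedded as reverse complements; `twin_mode` adds an
opposite-strand copy of every gene, forcing exactly zero codon↔anticodon
differences by construction.

**What the generators do not emulate:** linkage and coalescent structure,
mutation-rate heterogeneity along the genome (CpG effects, replication
timing), allele frequencies (variants are counted, not genotyped), selection,
splicing complexity (synthetic CDSs are single-exon), and real codon-usage
tables unless supplied.  Passing tests therefore demonstrate correctness of
the counting/pairing machinery and the statistical behaviour of the
estimators under the stated model — not that any particular real genome
complies with the symmetry.

## Strand-bias estimation

Within a comparison pair, a consistent strand orientation exists only when
one member has both interchange bases pyrimidine and its partner both
purine — 16 of the 44 pairs.  The mixed pairs blend (1+β)- and
(1−β)-weighted directed events, which under equal rates contributes no
signal and would dilute a pooled estimate toward zero.  The estimator
therefore pools only the 16 oriented pairs:
`β̂ = Σ(N_pyr − N_pur) / Σ(N_pyr + N_pur)` ∈ [−1, 1], with E[β̂] = β under
the generative model and sd ≈ √((1−β²)/n_oriented) (about 0.005 at 10⁵
variants, a third of which land in oriented classes).  Self-complementary
classes never enter.

## Problem sizes used in the tests

The parity-regime demonstration uses 3×10⁷ strand-symmetric variants on a
45 Mb genome: with ~6×10⁵ counts per comparison pair the per-pair noise is
200/√S ≈ 0.25%, so all 44 pairs fall below 1% — the package's chosen
operating point for reproducing the sub-percent parity observed in
population variant databases, whose catalogues are of comparable or larger
size (a 10⁶-variant set has ~1.4% noise per pair and cannot exhibit
sub-percent parity for all pairs).  Indel parity uses 2×10⁶ events
(per-pair noise 0.8%, tested against a 3% envelope); bias recovery uses
10⁵ variants against a ±0.02 tolerance (~3.7 sd).  Construction-based
checks (perfect-CSPR genomes, twin CDS sets) are exact at any size and use
0.1–0.3 Mb inputs.

## Known limitations

* VCF leniency is record-level: semantically invalid records (POS ≤ 0,
  symbolic or non-ACGT alleles) are skipped with a log line, but a
  structurally broken file fails in the parser regardless of `--strict`.
* Indels longer than one base and MNPs are tallied, never classified; there
  is no realignment.
* The skew module emits TSV profiles only; no plotting.
* The TA-skew sign convention is (A−T)/(A+T); sources differ on sign only,
  and the convention is stated in the report header.
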