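"""Seeded generators for genomes, variant sets and CDS sets.

These generators emulate the statistical structure of population-scale
variant databases and curated CDS catalogues, so that every analysis stage is
testable at a chosen scale without external downloads.

The substitution model is parameterized by six pyrimidine-anchored base rates
(C>A, C>G, C>T, T>A, T>C, T>G) plus a single strand-bias scalar beta in
[-1, 1]: a substitution of type t at a pyrimidine site occurs at rate
``r_t * (1 + beta)``, and the reverse-complement type at a purine site at
``r_t * (1 - beta)``.  beta = 0 is the no-strand-bias (parity-rule-2) regime,
under which the expected contextual spectrum is exactly strand-symmetric and
the parity deviations of the tabulated spectrum are pure sampling noise (per
comparison pair with total count S, the percentage-difference statistic has
standard deviation ~ 200/sqrt(S)).  A 12-rate expert mode
(``directed_rates``) can violate parity arbitrarily.

Variant sites are drawn without replacement (every site mutated at most once,
matching a "counted once" database), with inclusion probability proportional
to the site's total rate, via exponential-race keys.  Length-1 indels are
generated analogously, the deleted/inserted base weighted by the same
(1 +/- beta) factor.

All outputs are pure functions of (config, seed): identical seeds give
byte-identical genomes, VCFs and CDS sets.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._alphabet import COMP_CODE
from .io import Genome
from .seqsym import reverse_complement
from .snv_spectrum import PairingScheme, default_scheme
from .variants import DEL, INS, SNV, SpectrumTable, VariantTable
from .codon_composition import CdsRecord

__all__ = ["SimulationConfig", "CdsSimulationConfig", "simulate_genome",
           "simulate_variants", "simulate_cds_set", "SimulatedCdsSet",
           "estimate_strand_bias", "position_weighted_codon_table"]

PYRIMIDINE_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_CODE = {b: i for i, b in enumerate("ACGT")}
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS = tuple(sorted(a + b + c
                            for a in "ACGT" for b in "ACGT" for c in "ACGT"
                            if a + b + c not in STOP_CODONS))


@dataclass
class CdsSimulationConfig:
    """Gene-set generation settings.

    Genes are iid codon strings drawn from ``codon_weights`` (uniform over
    the 61 sense codons by default, with no enforced start/stop bookends so
    configured per-position compositions hold exactly in expectation).
    ``minus_fraction`` of genes are embedded on the minus strand (as reverse
    complements at their loci); ``twin_mode`` additionally emits, for every
    gene, a second gene with the identical CDS on the opposite strand,
    which forces exact codon/anticodon parity by construction.
    """

    n_genes: int = 200
    gene_length: int = 300  # bases, multiple of 3
    minus_fraction: float = 0.5
    codon_weights: dict[str, float] | None = None
    twin_mode: bool = False
    spacer_length: int = 20


@dataclass
class SimulationConfig:
    """Seeded generative settings for genomes, variants and CDS sets."""

    seed: int | None = None
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 1_000_000),)
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    genome_mode: str = "iid"  # or "perfect_cspr"
    n_snvs: int = 0
    n_indels: int = 0
    substitution_rates: dict[str, float] = field(
        default_factory=lambda: {t: 1.0 for t in PYRIMIDINE_TYPES})
    directed_rates: dict[str, float] | None = None  # 12-rate expert mode
    strand_bias: float = 0.0
    validated_fraction: float = 1.0
    cds: CdsSimulationConfig = field(default_factory=CdsSimulationConfig)

    def __post_init__(self):
        freqs = tuple(float(f) for f in self.base_frequencies)
        if abs(sum(freqs) - 1.0) > 1e-9 or any(f < 0 for f in freqs):
            raise ValueError("base_frequencies must be non-negative and sum to 1")
        self.base_frequencies = freqs
        if not -1.0 <= self.strand_bias <= 1.0:
            raise ValueError("strand_bias must be in [-1, 1]")
        rates = {t: float(self.substitution_rates.get(t, 0.0))
                 for t in PYRIMIDINE_TYPES}
        if any(r < 0 for r in rates.values()) or not any(rates.values()):
            raise ValueError("substitution rates must be >= 0 and not all 0")
        self.substitution_rates = rates

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load from a flat key=value text file (CLI config format)."""
        kwargs: dict = {}
        cds_kwargs: dict = {}
        rates: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key == "chromosomes":
                    chroms = []
                    for token in value.split(","):
                        name, _, length = token.partition(":")
                        chroms.append((name.strip(), int(length)))
                    kwargs["chromosomes"] = tuple(chroms)
                elif key == "base_frequencies":
                    kwargs["base_frequencies"] = tuple(
                        float(v) for v in value.split(","))
                elif key.startswith("rate."):
                    rates[key[5:]] = float(value)
                elif key.startswith("cds."):
                    sub = key[4:]
                    caster = {"n_genes": int, "gene_length": int,
                              "minus_fraction": float,
                              "twin_mode": lambda v: v.lower() in ("1", "true", "yes"),
                              "spacer_length": int}[sub]
                    cds_kwargs[sub] = caster(value)
                elif key in ("seed", "n_snvs", "n_indels"):
                    kwargs[key] = int(value)
                elif key in ("strand_bias", "validated_fraction"):
                    kwargs[key] = float(value)
                elif key == "genome_mode":
                    kwargs[key] = value
                else:
                    raise ValueError(f"unknown config key {key!r}")
        if rates:
            kwargs["substitution_rates"] = rates
        if cds_kwargs:
            kwargs["cds"] = CdsSimulationConfig(**cds_kwargs)
        return cls(**kwargs)


def _rng(config: SimulationConfig,
         rng: "np.random.Generator | int | None") -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    seed = rng if rng is not None else config.seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genomes

def simulate_genome(config: SimulationConfig,
                    rng: "np.random.Generator | int | None" = None) -> Genome:
    """Draw a genome under the configured mode.

    ``iid`` draws bases independently from ``base_frequencies``;
    ``perfect_cspr`` emits s + reverse_complement(s) per chromosome (even
    length required), a sequence that equals its own reverse complement and
    therefore satisfies exact k-mer parity for every k.
    """
    gen = _rng(config, rng)
    chroms: dict[str, np.ndarray] = {}
    for name, length in config.chromosomes:
        if length <= 0:
            raise ValueError(f"chromosome {name} must have positive length")
        if config.genome_mode == "iid":
            codes = gen.choice(4, size=length,
                               p=config.base_frequencies).astype(np.uint8)
        elif config.genome_mode == "perfect_cspr":
            if length % 2:
                raise ValueError("perfect_cspr chromosomes need even length")
            half = gen.choice(4, size=length // 2,
                              p=config.base_frequencies).astype(np.uint8)
            codes = np.concatenate([half, COMP_CODE[half[::-1]]])
        else:
            raise ValueError(f"unknown genome_mode {config.genome_mode!r}")
        chroms[name] = codes
    return Genome(chroms)


# ---------------------------------------------------------------------------
# variants

def _directed_rate_matrix(config: SimulationConfig) -> np.ndarray:
    """4x4 matrix of directed rates r[ref, alt] including the beta factor."""
    rates = np.zeros((4, 4))
    beta = config.strand_bias
    if config.directed_rates is not None:
        for key, value in config.directed_rates.items():
            ref, alt = key.split(">")
            rates[_CODE[ref], _CODE[alt]] = float(value)
        return rates
    for key, value in config.substitution_rates.items():
        ref, alt = key.split(">")
        rates[_CODE[ref], _CODE[alt]] = value * (1.0 + beta)
        # reverse-complement type at the purine site
        rc_ref, rc_alt = 3 - _CODE[ref], 3 - _CODE[alt]
        rates[rc_ref, rc_alt] = value * (1.0 - beta)
    return rates


def _weighted_sample_without_replacement(weights: np.ndarray, n: int,
                                         gen: np.random.Generator) -> np.ndarray:
    """Indices of n items drawn without replacement, inclusion ordered by
    exponential races with rate = weight (Efraimidis–Spirakis style)."""
    if n > weights.size:
        raise ValueError(f"requested {n} draws from {weights.size} items")
    if n == weights.size:
        return np.arange(n)
    keys = gen.exponential(size=weights.size) / weights
    return np.argpartition(keys, n)[:n]


def _eligible_sites(genome: Genome, names: Sequence[str]):
    """Global 0-based concatenated coordinates of non-edge, non-N sites."""
    offsets = [0]
    pieces = []
    for name in names:
        codes = genome.codes(name)
        idx = np.arange(1, codes.size - 1, dtype=np.int64)
        idx = idx[codes[idx] != 4]
        pieces.append(idx + offsets[-1])
        offsets.append(offsets[-1] + codes.size)
    return np.concatenate(pieces), np.asarray(offsets)


def _split_global(global_pos: np.ndarray, offsets: np.ndarray):
    chrom_idx = (np.searchsorted(offsets, global_pos, side="right") - 1)
    local = global_pos - offsets[chrom_idx]
    return chrom_idx.astype(np.int32), local


def simulate_variants(genome: Genome, config: SimulationConfig,
                      rng: "np.random.Generator | int | None" = None
                      ) -> VariantTable:
    """Simulate ``n_snvs`` SNVs and ``n_indels`` length-1 indels.

    SNV sites are sampled without replacement with probability proportional
    to the site's total substitution rate; the alt allele is then drawn from
    the directed rates at that ref base.  Deletion sites and inserted bases
    are weighted by the same pyrimidine/purine (1 +/- beta) factor.  The
    returned table is REF-consistent with ``genome`` by construction and
    sorted by coordinate; a ``validated_fraction`` of records carries the
    VLD flag when serialized.
    """
    gen = _rng(config, rng)
    names = genome.names
    all_codes = np.concatenate([genome.codes(n) for n in names])
    rates = _directed_rate_matrix(config)
    site_rate = rates.sum(axis=1)  # total rate per ref base

    parts = []  # (chrom_idx, pos1, kind, base)
    sites, offsets = _eligible_sites(genome, names)

    if config.n_snvs:
        weights = site_rate[all_codes[sites]]
        ok = weights > 0
        chosen = sites[ok][_weighted_sample_without_replacement(
            weights[ok], config.n_snvs, gen)]
        refs = all_codes[chosen]
        alts = np.empty(config.n_snvs, dtype=np.uint8)
        for b in range(4):
            mask = refs == b
            count = int(mask.sum())
            if not count:
                continue
            p = rates[b] / rates[b].sum()
            alts[mask] = gen.choice(4, size=count, p=p).astype(np.uint8)
        chrom_idx, local = _split_global(chosen, offsets)
        parts.append((chrom_idx, local + 1, np.full(config.n_snvs, SNV,
                                                    dtype=np.int8), alts))

    if config.n_indels:
        beta = config.strand_bias
        base_w = np.array([1.0 - beta, 1.0 + beta, 1.0 - beta, 1.0 + beta, 0.0])
        n_del = int(gen.binomial(config.n_indels, 0.5))
        n_ins = config.n_indels - n_del
        if n_del:
            weights = base_w[all_codes[sites]]
            ok = weights > 0
            chosen = sites[ok][_weighted_sample_without_replacement(
                weights[ok], n_del, gen)]
            chrom_idx, local = _split_global(chosen, offsets)
            # anchor = base before the deleted one; POS = its 1-based coord
            parts.append((chrom_idx, local, np.full(n_del, DEL, dtype=np.int8),
                          all_codes[chosen]))
        if n_ins:
            junctions = sites  # anchor j: insert between j and j+1
            chosen = junctions[gen.choice(junctions.size, size=n_ins,
                                          replace=False)]
            inserted = gen.choice(4, size=n_ins,
                                  p=base_w[:4] / base_w[:4].sum()).astype(np.uint8)
            chrom_idx, local = _split_global(chosen, offsets)
            parts.append((chrom_idx, local + 1,
                          np.full(n_ins, INS, dtype=np.int8), inserted))

    if parts:
        chrom_idx = np.concatenate([p[0] for p in parts])
        pos = np.concatenate([p[1] for p in parts]).astype(np.int64)
        kind = np.concatenate([p[2] for p in parts])
        base = np.concatenate([p[3] for p in parts]).astype(np.uint8)
    else:
        chrom_idx = np.empty(0, dtype=np.int32)
        pos = np.empty(0, dtype=np.int64)
        kind = np.empty(0, dtype=np.int8)
        base = np.empty(0, dtype=np.uint8)
    if config.validated_fraction >= 1.0:
        validated = np.ones(pos.size, dtype=bool)
    else:
        validated = gen.random(pos.size) < config.validated_fraction
    return VariantTable(list(names), chrom_idx, pos, kind, base,
                        validated).sort()


# ---------------------------------------------------------------------------
# CDS sets

def position_weighted_codon_table(p1: Sequence[float], p2: Sequence[float],
                                  p3: Sequence[float],
                                  exclude_stops: bool = True
                                  ) -> dict[str, float]:
    """Codon weights with independent per-position base distributions
    (order A, C, G, T per position); stop codons excluded by default."""
    weights = {}
    for i, a in enumerate("ACGT"):
        for j, b in enumerate("ACGT"):
            for k, c in enumerate("ACGT"):
                codon = a + b + c
                if exclude_stops and codon in STOP_CODONS:
                    continue
                w = p1[i] * p2[j] * p3[k]
                if w > 0:
                    weights[codon] = w
    return weights


@dataclass
class SimulatedCdsSet:
    """A simulated gene set: records, the genome carrying them, and the
    interval-table rows (cds_id, chrom, strand, exons)."""

    records: list[CdsRecord]
    genome: Genome
    table_rows: list[tuple[str, str, str, tuple[tuple[int, int], ...]]]

    def write_table(self, path) -> None:
        with open(path, "w") as fh:
            for cds_id, chrom, strand, exons in self.table_rows:
                exon_str = ",".join(f"{s}-{e}" for s, e in exons)
                fh.write(f"{cds_id}\t{chrom}\t{strand}\t{exon_str}\n")


def simulate_cds_set(config: SimulationConfig,
                     rng: "np.random.Generator | int | None" = None
                     ) -> SimulatedCdsSet:
    """Simulate a CDS set embedded in a genome.

    Genes are placed non-overlapping, separated by iid spacer sequence, on
    the configured chromosomes in order; a placement error is raised if
    they do not fit.
    """
    gen = _rng(config, rng)
    cds = config.cds
    if cds.gene_length < 3 or cds.gene_length % 3:
        raise ValueError("gene_length must be a positive multiple of 3")
    weights = cds.codon_weights or {c: 1.0 for c in SENSE_CODONS}
    codon_list = sorted(weights)
    probs = np.array([weights[c] for c in codon_list], dtype=float)
    probs /= probs.sum()

    n_codons = cds.gene_length // 3
    genes: list[tuple[str, str, str]] = []  # (id, strand, cds_seq)
    for i in range(cds.n_genes):
        idx = gen.choice(len(codon_list), size=n_codons, p=probs)
        seq = "".join(codon_list[j] for j in idx)
        strand = "-" if gen.random() < cds.minus_fraction else "+"
        genes.append((f"gene{i + 1:04d}", strand, seq))
        if cds.twin_mode:
            twin_strand = "+" if strand == "-" else "-"
            genes.append((f"gene{i + 1:04d}t", twin_strand, seq))

    chrom_seqs: dict[str, list[str]] = {}
    records: list[CdsRecord] = []
    rows = []
    chrom_iter = iter(config.chromosomes)
    try:
        chrom_name, chrom_cap = next(chrom_iter)
    except StopIteration:
        raise ValueError("no chromosomes configured")
    chrom_seqs[chrom_name] = []
    cursor = 0

    def spacer() -> str:
        draw = gen.choice(4, size=cds.spacer_length,
                          p=config.base_frequencies)
        return "".join("ACGT"[b] for b in draw)

    for gene_id, strand, seq in genes:
        needed = cds.spacer_length + len(seq)
        while cursor + needed + cds.spacer_length > chrom_cap:
            try:
                chrom_name, chrom_cap = next(chrom_iter)
            except StopIteration:
                raise ValueError("genes do not fit on configured chromosomes")
            chrom_seqs[chrom_name] = []
            cursor = 0
        chrom_seqs[chrom_name].append(spacer())
        cursor += cds.spacer_length
        start = cursor + 1  # 1-based
        embedded = seq if strand == "+" else reverse_complement(seq)
        chrom_seqs[chrom_name].append(embedded)
        cursor += len(seq)
        exons = ((start, cursor),)
        records.append(CdsRecord(gene_id, strand, seq, chrom=chrom_name,
                                 exons=exons))
        rows.append((gene_id, chrom_name, strand, exons))
    chrom_seqs[chrom_name].append(spacer())

    genome = Genome({name: "".join(parts)
                     for name, parts in chrom_seqs.items()})
    return SimulatedCdsSet(records, genome, rows)


# ---------------------------------------------------------------------------
# parameter recovery

def estimate_strand_bias(spectrum: SpectrumTable,
                         scheme: PairingScheme | None = None) -> float:
    """Pooled strand-bias estimate from an SNV spectrum.

    Uses the comparison pairs with an unambiguous strand orientation (one
    member has both interchange bases pyrimidine, its partner both purine;
    16 of the 44 pairs) and returns
    ``sum(N_pyr - N_pur) / sum(N_pyr + N_pur)`` in [-1, 1], the maximum-
    likelihood pooled estimate of beta under the generative model.
    Self-complementary classes never enter.  NaN when all pair counts are
    zero.
    """
    scheme = scheme or default_scheme()
    num = den = 0
    for pyr_key, pur_key in scheme.pyrimidine_oriented_pairs:
        a, b = spectrum.counts[pyr_key], spectrum.counts[pur_key]
        num += a - b
        den += a + b
    if den == 0:
        return math.nan
    return num / den
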