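"""Recovering a strand-bias parameter from a mutation spectrum.

Simulates variant sets at increasing strand bias beta (pyrimidine-site
substitutions up-weighted by 1+beta, purine-site by 1-beta) and shows that
the pooled parity statistic over the orientation-unambiguous comparison
pairs recovers beta.  beta = 0 is the no-strand-bias regime in which
intrastrand DNA symmetry is expected to hold.
"""
from csprkit import (estimate_strand_bias, simulate_genome, simulate_variants,
                     tabulate_snv_spectrum)
from csprkit.synthetic_data import SimulationConfig

print("true beta  ->  estimated beta_hat (n = 100,000 SNVs each)")
for beta in (0.0, 0.1, 0.2, 0.5):
    config = SimulationConfig(seed=7, chromosomes=(("chr1", 2_000_000),),
                              n_snvs=100_000, strand_bias=beta)
    genome = simulate_genome(config)
    spectrum = tabulate_snv_spectrum(simulate_variants(genome, config),
                                     genome)
    print(f"  {beta:4.1f}     ->  {estimate_strand_bias(spectrum):+.4f}")
print("\nbeta_hat pools the 16 comparison pairs whose members are "
      "pyrimidine- vs purine-anchored;\nsampling sd at this n is ~0.005, "
      "so recovery is accurate to the second decimal.")
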