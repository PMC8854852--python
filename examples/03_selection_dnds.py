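"""Diversifying-selection signature: pairwise Nei-Gojobori dN/dS.

The generator concentrates nonsynonymous change at peptide-binding-region
codons, mimicking the hallmark of functional MHC loci.  The analysis
averages Jukes-Cantor-corrected dN and dS over all pairs of alleles
observed in each population and tests dN > dS with a codon-bootstrap
Z-test.
"""

from bolapop import (
    SimulationConfig,
    pairwise_dnds,
    population_dnds,
    simulate_allele_pool,
    simulate_metapopulation,
)

cfg = SimulationConfig(seed=3)
pool = simulate_allele_pool(cfg)
genotypes = simulate_metapopulation(cfg, pool)

a, b = sorted(pool.sequences)[:2]
d_n, d_s = pairwise_dnds(pool.sequences[a], pool.sequences[b])
print(f"single pair {a} vs {b}: dN = {d_n:.4f}, dS = {d_s:.4f}")

print(f"\n{'population':<12}{'dN':>8}{'dS':>8}{'dN/dS':>8}{'Z':>8}{'p':>10}{'pairs':>7}")
for pop in genotypes.populations():
    r = population_dnds(genotypes, pool, pop, n_boot=1000, seed=3)
    print(f"{pop:<12}{r.d_n:>8.3f}{r.d_s:>8.3f}{r.ratio:>8.2f}"
          f"{r.z:>8.2f}{r.p:>10.4f}{r.n_pairs:>7}")

print("\nA ratio well above 1 with a small one-tailed p indicates an excess")
print("of amino-acid-changing substitutions, i.e. diversifying selection on")
print("the peptide-binding codons.")
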