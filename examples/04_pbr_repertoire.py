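"""Peptide-binding-region repertoire comparison across populations.

Computes within-population identity/similarity (all 2N-copy pairs, so
homozygosity raises identity), per-population PBR amino-acid profiles,
their Pearson correlation matrix with a global summary, pocket-wise
correlations and a UPGMA dendrogram.
"""

from bolapop import (
    SimulationConfig,
    default_pbr_mask,
    pbr_profile,
    population_similarity,
    profile_correlation,
    simulate_allele_pool,
    simulate_metapopulation,
    upgma,
)

cfg = SimulationConfig(seed=4, n_populations=4, n_individuals=60)
pool = simulate_allele_pool(cfg)
genotypes = simulate_metapopulation(cfg, pool)
mask = default_pbr_mask()

print(f"{'population':<12}{'region':<8}{'identity':>12}{'similarity':>12}")
for pop in genotypes.populations():
    for region in ("beta1", "pbr"):
        s = population_similarity(genotypes, pool, pop, region=region, mask=mask)
        print(f"{pop:<12}{region:<8}{s.identity_mean:>7.2f}({s.identity_sd:.1f})"
              f"{s.similarity_mean:>7.2f}({s.similarity_sd:.1f})")

profiles = [pbr_profile(genotypes, pool, p, mask) for p in genotypes.populations()]
matrix, global_pcc = profile_correlation(profiles)
print(f"\nglobal PBR profile correlation (mean off-diagonal PCC): {global_pcc:.3f}")
for pocket in sorted(mask.pockets):
    _, gp = profile_correlation(profiles, pocket=pocket)
    print(f"  pocket {pocket}: PCC = {gp:.3f}")
print("\nUPGMA dendrogram on d = 1 - PCC:")
print(" ", upgma(matrix))
print("\nHigh correlations mean the populations expose nearly the same")
print("amino-acid spectrum at peptide-contact positions, i.e. similar")
print("potential MHC-presented peptide repertoires despite allele turnover.")
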