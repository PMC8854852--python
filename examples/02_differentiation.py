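"""Population differentiation: pairwise F_ST, Nei D_A and PCA.

Simulates four populations diverged from a shared ancestral allele pool
under a Balding-Nichols model with target F_ST = 0.1, then estimates
pairwise Weir-Cockerham theta (with permutation p-values), Nei's D_A
distance and an allele-frequency PCA.
"""

from bolapop import (
    SimulationConfig,
    allele_frequencies,
    distance_matrix,
    frequency_pca,
    simulate_allele_pool,
    simulate_metapopulation,
)

cfg = SimulationConfig(seed=2, n_populations=4, fst_target=0.1, inbreeding_f=0.0,
                       n_individuals=100)
pool = simulate_allele_pool(cfg)
genotypes = simulate_metapopulation(cfg, pool)

fst = distance_matrix(genotypes, "fst", n_perm=500, seed=2)
da = distance_matrix(genotypes, "da")

print("pairwise Weir-Cockerham theta (permutation p in parentheses):")
for i, a in enumerate(fst.labels):
    for b in fst.labels[i + 1:]:
        j = fst.labels.index(b)
        print(f"  {a} vs {b}: {fst.get(a, b):.4f} (p={fst.p_values[i, j]:.3f})")
print(f"mean off-diagonal theta: {fst.mean_offdiagonal():.4f}"
      f"  (generator target was {cfg.fst_target})")
print(f"mean Nei D_A distance:   {da.mean_offdiagonal():.4f}")

pca = frequency_pca([allele_frequencies(genotypes, p) for p in fst.labels])
print("\nPCA of the populations-by-alleles frequency matrix:")
for lab, row in zip(pca.labels, pca.scores):
    print(f"  {lab}: PC1={row[0]:+.4f}  PC2={row[1]:+.4f}")
print("variance explained: "
      + ", ".join(f"PC{k+1} {v:.1f}%" for k, v in enumerate(pca.variance_explained)))
print("Populations drawn from the same ancestral pool scatter around the")
print("origin; theta near the target confirms the divergence model.")
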