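# bolapop

Single-locus MHC population-diversity analysis for highly polymorphic,
codominantly typed loci, built around the class II **BoLA-DRB3** exon 2
locus of cattle.  The second exon encodes the β1 domain of the DR β chain,
whose peptide-binding-region (PBR) positions determine which peptides an
allele can present to CD4⁺ T cells; comparing its allele spectra across
populations therefore speaks both to herd genetic diversity and to
population-level immune repertoire.

The package is aimed at animal-genetics and immunogenetics researchers who
have, per individual, a population label and two allele names, plus
codon-aligned nucleotide sequences for the alleles.  It provides, as an
importable library with a thin CLI:

* **Allele frequencies** by direct counting with maximum-likelihood
  standard errors `se = sqrt(p(1−p)/2N)`, and shared-allele summaries
  (mean cumulative frequency of the alleles two populations share).
* **Heterozygosity and Hardy–Weinberg testing** — observed h_o, unbiased
  expected h_e = (2N/(2N−1))(1 − Σp²), the fixation index
  F_IS = 1 − h_o/h_e, and a Monte-Carlo exact test that conditions on
  allele counts by re-pairing the 2N gene copies.
* **Rarefaction allelic richness** R_s(g) = Σᵢ [1 − C(2N−cᵢ, g)/C(2N, g)],
  the expected allele count in a standardized subsample of g gene copies.
* **Differentiation** — pairwise Weir–Cockerham θ (variance-component
  F_ST) with permutation significance, Nei's D_A = 1 − Σ√(xᵢyᵢ), and
  covariance PCA of the populations-by-alleles frequency matrix.
* **Selection signatures** — pairwise Nei–Gojobori dN/dS with
  Jukes–Cantor correction d = −(3/4)ln(1 − 4p/3), averaged over the
  alleles observed in each population, with a codon-bootstrap Z-test for
  dN > dS (diversifying selection).
* **PBR repertoire comparison** — BLOSUM62 identity/similarity within
  populations (over all 2N allele-copy pairs, so homozygosity raises
  identity), per-population PBR amino-acid frequency profiles
  (31 positions × 20 residues → 620-coordinate vectors), their Pearson
  correlation matrix with pocket-wise restriction, and UPGMA clustering
  on d = 1 − r.
* **A synthetic-data generator** producing allele pools with excess
  nonsynonymous change at PBR codons, Balding–Nichols population
  divergence with a target F_ST, and genotype sampling under an
  inbreeding coefficient F — so the entire pipeline is testable without
  access to any typing data.

## Worked example

```bash
python examples/01_simulate_and_diversity.py
```

```
population      N  N_a     R_s     h_o     h_e    F_IS     HWE p
pop1           60   21    21.0   0.733   0.928   0.210    0.0005
pop2           60   17    17.0   0.650   0.863   0.247    0.0005

Richness is standardized to g = 120 gene copies.
```

Two simulated populations of 60 animals each carry 21 and 17 distinct
alleles; expected heterozygosity is high (as typical for MHC loci) but
observed heterozygosity falls short of it, giving positive F_IS ≈ 0.21–0.25
and a significant exact-test p — recovering the inbreeding coefficient
F = 0.25 the generator used.  The other example scripts demonstrate
differentiation (F_ST/D_A/PCA), the dN/dS Z-test, the PBR profile
correlation with UPGMA dendrogram, and a frequency-only reanalysis of the
embedded published cohort tables.

The same analyses are available from a shell:

```bash
bolapop simulate --outdir sim --seed 1
bolapop diversity --genotypes sim/genotypes.tsv
bolapop dnds --genotypes sim/genotypes.tsv --fasta sim/alleles.fasta
bolapop report --config run.json     # full pipeline, one JSON report
```

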