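# Methods

## Scope and data model

All analyses operate on a single codominant locus.  The inputs are a
genotype table (sample, population, two allele names), a set of
codon-aligned nucleotide allele sequences with no ambiguity codes and no
stop codons, and a peptide-binding-region (PBR) mask of 1-based amino-acid
positions, optionally partitioned into binding pockets.  Allele order
within an individual is treated as meaningless and stored sorted.  A
configurable translation offset maps published domain numbering onto the
alignment, since alignments rarely begin at residue 1 of the β1 domain.

## Frequency and diversity estimators

Allele frequencies are direct copy counts, `p = c/2N`, the ML estimator
for a codominant locus; its standard error is `sqrt(p(1−p)/2N)`, which is
zero exactly at fixation.  Observed heterozygosity h_o is the fraction of
individuals with two distinct allele names.  Expected heterozygosity uses
the small-sample unbiased correction `h_e = (2N/(2N−1))(1 − Σp²)`.

The fixation index is reported as the Nei-style point estimate
`F_IS = 1 − h_o/h_e` with unbiased h_e.  Small-sample variance-component
estimators (as implemented in common F-statistics packages) differ from
this in the third decimal; the Nei form was chosen because it is exactly
determined by (h_o, h_e) and therefore auditable from the printed summary
columns alone.

### Exact Hardy–Weinberg test

The exact test is a Monte-Carlo permutation conditioned on allele counts:
the 2N gene copies are pooled, shuffled and re-paired into N genotypes;
the statistic is F_IS of the permuted table.  Because h_e is fixed under
this conditioning, `F_perm ≥ F_obs` is equivalent to `h_o,perm ≤ h_o,obs`,
giving a one-sided heterozygote-deficit test.  The p-value uses the
add-one estimator `(1 + #{F_perm ≥ F_obs})/(1 + n_perm)` (default
n_perm = 10,000), which can never return zero.  For N ≤ 5 the test is
checked against exhaustive enumeration of all perfect matchings of the
gene copies.  Note that, as for any exact test of a discrete statistic,
the null distribution of p-values is conservative rather than exactly
uniform; the test suite checks one-sided validity (P(p ≤ α) ≤ α plus
Monte-Carlo slack), not strict uniformity.

### Rarefaction richness

Allelic richness is hypergeometric rarefaction,
`R_s(g) = Σᵢ [1 − C(2N−cᵢ, g)/C(2N, g)]`, evaluated in log space via
`gammaln` so cohorts of hundreds of animals pose no overflow risk.  The
standardized subsample defaults to `g = 2·min(N)` over the populations
being compared — the largest g valid for all of them — and can be
overridden.  `R_s(2N) = N_a` exactly, and R_s is nondecreasing in g.

## Differentiation

Pairwise F_ST is the Weir–Cockerham variance-component estimator θ for
r = 2 populations, summing the among-population component a and the total
a+b+c over alleles before taking the ratio.  Negative estimates are
reported as computed, not truncated at zero, so near-zero differentiation
is visible as such.  Significance comes from permuting individuals between
the two populations (default 1,000 permutations, add-one estimator).  θ is
a ratio estimator, so its expectation under the generator is checked by
simulation rather than algebra (see below).

Nei's D_A between frequency vectors is `1 − Σ√(xᵢyᵢ)` over the union of
alleles; it is symmetric and bounded in [0, 1] but not a metric, and no
triangle property is assumed.  PCA operates on the populations-by-alleles
matrix with zeros for absent alleles, column-centered, decomposing the
covariance (all columns share the frequency scale, so correlation scaling
would inflate rare alleles).  Components are signed so each component's
first nonzero loading is positive; identical populations are flagged
degenerate with zero variance shares.

## dN/dS

Synonymous site counts per codon are the Nei–Gojobori fractions: for each
position, the share of the three possible substitutions that preserve the
amino acid (changes to stop codons count as nonsynonymous).  Differences
between codons are classified by enumerating all orderings of the
differing positions; pathways crossing a stop codon get zero weight and
the remainder are weighted equally.  Proportions `p_S = S_d/S` and
`p_N = N_d/N` receive the Jukes–Cantor correction
`d = −(3/4)ln(1 − 4p/3)`, undefined (flagged saturated) at p ≥ 3/4;
saturated pairs are excluded from population averages with a warning.

Population-level d_N and d_S are unweighted means over all unordered pairs
of distinct alleles observed in the population — mirroring how sequence
collections are usually averaged — with a frequency-weighted mode
(pair weight `pᵢpⱼ`) available for repertoire-style questions where common
alleles should dominate.  The Z statistic is
`(d_N − d_S)/sqrt(V(d_N) + V(d_S))` with variances from bootstrap over
codon sites (default 1,000 resamples, shared codon indices across pairs),
and the one-tailed normal p targets the positive-selection alternative
d_N > d_S.  An analytic variance is deliberately not attempted; the
bootstrap matches common practice for the codon-based Z-test.

## PBR repertoire

Pairwise peptide identity is the percent of positions with equal residues;
similarity additionally counts residue pairs with a positive BLOSUM62
score.  Within a population, the default `copies` mode scores all
C(2N, 2) unordered pairs of the 2N allele copies, so a homozygote's two
identical copies contribute a 100/100 pair: high homozygosity legitimately
raises within-population identity, which is the quantity of interest when
arguing about individual repertoire size.  A `unique` mode restricted to
distinct alleles is provided for allele-centric questions.  Reported
spreads are population standard deviations (ddof = 0) over the weighted
pair set.

Each population's PBR profile is a positions × 20 row-stochastic
amino-acid frequency matrix over its distinct observed alleles (each
counted once by default; frequency weighting optional), flattened
row-major with residues in fixed alphabetical order — 620 coordinates for
a full 31-position mask.  Profiles are compared by Pearson correlation,
either on full vectors or restricted to one pocket's positions; the
"global" correlation is defined as the mean off-diagonal coefficient, a
choice recorded in output metadata since no standard definition exists.
Clustering is UPGMA on `d = 1 − r` (the simplest monotone distance on
correlations), implemented directly with size-weighted averaging,
deterministic lexicographic tie-breaking and Newick output; the result is
ultrametric by construction.

### Default mask

The shipped default mask contains the 28 β1 positions named in published
accounts of this locus as variable, invariable or under diversifying
selection (9, 10, 11, 12, 13, 14, 15, 26, 29, 30, 32, 37, 38, 40, 47, 57,
64, 67, 70, 71, 74, 77, 78 plus 72, 73, 79, 82, 83).  It is documented as
an incomplete stand-in for the full 31-position MHC-DRB PBR definition;
analyses that must reproduce a specific published 620-coordinate setup
should supply the complete mask file.  The default pocket assignments
(P1/P4/P6/P7/P9) are synthetic defaults derived from the classical MHC-DRB
pocket architecture restricted to masked positions, and are likewise
user-overridable.

## Synthetic data generator

The generator emulates the statistical structure of a multi-population
MHC typing study:

* **Allele pool** — a random ancestral sequence of sense codons; each
  further allele is an independently mutated copy, with synonymous changes
  at Poisson intensity `mu_syn` per codon (default 0.01) everywhere and
  nonsynonymous changes at `mu_nonsyn_pbr` (default 0.35) at PBR codons,
  stop codons avoided by rejection.  The defaults produce pairwise
  divergences around d_N ≈ 0.1 at d_S ≈ 0.03 — the order observed at
  functional MHC exons — so pooled dN/dS sits well above 1.
* **Population frequencies** — ancestral frequencies
  Dirichlet(concentration 1), then per-population divergence by the
  multi-allele Balding–Nichols form: Dirichlet with concentration
  `p·(1−F_ST)/F_ST`, whose per-allele marginals are the classical
  Beta(p(1−F)/F, (1−p)(1−F)/F) with variance `p(1−p)F_ST`.
* **Genotypes** — per individual the stream draws (u, a, b) in fixed
  order; if `u < F` the individual is autozygous (b ← a).  The fixed draw
  order couples runs with the same seed across inbreeding levels, which
  makes monotonicity checks (e.g. identity versus F) far less noisy.

Default cohort shape: 40 alleles × 89 codons, 2 populations × 60
individuals, F_ST = 0.05, F = 0.25 — matching the size and heterozygote
deficit of a realistic two-breed MHC typing study.  A single
`numpy.random.Generator` seeded from the config drives every draw in
documented order, so all outputs are reproducible bit-for-bit.

What the generator does **not** emulate: linkage to other loci,
recombination or gene conversion (a known generator of MHC alleles),
genotyping error and allelic dropout, population substructure below the
population label (Wahlund effects must be induced explicitly by simulating
subpopulations), and selection acting on genotype sampling rather than on
sequence divergence.  Passing tests therefore validate the estimators
under a clean single-locus model, not robustness to those artefacts.

## Validation design and problem sizes

Estimators with closed combinatorial structure are tested for exact
agreement with brute-force oracles: rarefaction against enumeration of all
subsamples for 2N ≤ 12, pathway counting against explicit codon-chain
enumeration, the Monte-Carlo HWE p against exhaustive pairing enumeration
for N ≤ 5.  Stochastic recovery checks average 20 seeds at N = 500 per
population: mean F_IS within ±0.05 of F ∈ {0, 0.1, 0.3} and mean pairwise
θ within ±0.02 of F_ST ∈ {0.05, 0.1} (the θ check uses F = 0, since
Weir–Cockerham θ assumes random mating within populations).  The
identity-versus-inbreeding monotonicity check uses N = 12 with 100 coupled
seeds, because the copies-mode homozygosity effect scales as 1/(2N−1) and
would be invisible at large N.  These sizes keep the full suite under a
minute while leaving each check comfortably inside its tolerance.

## Known limitations

* Single locus only: no multi-locus F-statistics, no bootstrap over loci.
* The exact HWE test is Monte-Carlo, not the full Markov-chain enumeration;
  for very large allele counts the permutation null is the practical
  choice but p-values carry Monte-Carlo noise of order `1/sqrt(n_perm)`.
* F_IS significance and the HWE p are the same permutation test viewed
  through two statistics; they are reported separately for table parity
  but are not independent evidence.
* The dN/dS bootstrap treats codon sites as exchangeable, ignoring any
  spatial clustering of selected codons.
* D_A and θ are reported without multiple-testing correction; users
  comparing many population pairs should correct downstream.
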