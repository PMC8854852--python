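"""Allele frequencies, heterozygosity, F_IS and the exact Hardy-Weinberg test.

Frequencies are obtained by direct counting of allele copies; for a
codominant locus this is the maximum-likelihood estimator, with standard
error sqrt(p(1-p)/2N).  Observed heterozygosity h_o is the fraction of
individuals carrying two different alleles; expected heterozygosity uses
the small-sample unbiased form h_e = (2N/(2N-1)) (1 - sum p_i^2).  The
within-population fixation index is F_IS = 1 - h_o/h_e, and departure from
Hardy-Weinberg proportions is tested by a Monte-Carlo exact test that
conditions on the observed allele counts: the 2N gene copies are pooled,
shuffled and re-paired into N genotypes, and F_IS of each permuted table is
compared with the observed value (one-sided, heterozygote deficit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_model import (
    AlleleFrequency,
    FrequencyTable,
    GenotypeTable,
    ValidationError,
)

__all__ = [
    "DiversityStats",
    "ml_standard_error",
    "allele_frequencies",
    "shared_allele_summary",
    "observed_heterozygosity",
    "expected_heterozygosity_unbiased",
    "f_is",
    "hwe_exact_test",
    "diversity_stats",
    "size_effect_correlation",
]


@dataclass(frozen=True)
class DiversityStats:
    """Per-population single-locus diversity summary.

    ``f_is`` and the p-values are ``None`` for a monomorphic population,
    where the fixation index is undefined.
    """

    population: str
    n: int
    n_a: int
    h_o: float
    h_e: float
    f_is: float | None
    f_is_p: float | None
    hwe_p: float | None

    def __post_init__(self):
        if self.n_a < 1:
            raise ValidationError("n_a must be >= 1")
        if not (0 <= self.h_o <= 1 and 0 <= self.h_e <= 1):
            raise ValidationError("heterozygosities must lie in [0, 1]")


def ml_standard_error(p: float, n_individuals: int) -> float:
    """Standard error of a counting (ML) allele-frequency estimate,
    sqrt(p(1-p)/2N); zero exactly when p is 0 or 1."""
    return math.sqrt(p * (1.0 - p) / (2 * n_individuals))


def allele_frequencies(g: GenotypeTable, population: str) -> FrequencyTable:
    """Allele frequencies for one population by direct copy counting."""
    counts = g.allele_counts(population)
    n = g.n(population)
    copies = 2 * n
    alleles = {
        name: AlleleFrequency(p=c / copies, se=ml_standard_error(c / copies, n), count=c)
        for name, c in sorted(counts.items())
    }
    return FrequencyTable(population=population, alleles=alleles, n_individuals=n)


def _freq_map(f) -> dict[str, float]:
    if isinstance(f, FrequencyTable):
        return {name: a.p for name, a in f.alleles.items() if a.count > 0}
    return {name: p for name, p in dict(f).items() if p > 0}


def shared_allele_summary(fa, fb) -> tuple[set[str], float]:
    """Alleles segregating in both populations and their mean cumulative
    frequency.

    The summary is the mean, over the two populations, of the summed
    frequency of the shared alleles within each population.  Accepts
    :class:`FrequencyTable` objects or plain ``{allele: frequency}``
    mappings (e.g. transcribed published frequency columns).
    """
    ma, mb = _freq_map(fa), _freq_map(fb)
    shared = set(ma) & set(mb)
    cum_a = sum(ma[x] for x in shared)
    cum_b = sum(mb[x] for x in shared)
    return shared, (cum_a + cum_b) / 2.0


def observed_heterozygosity(g: GenotypeTable, population: str) -> float:
    recs = g.population_records(population)
    return sum(1 for r in recs if not r.is_homozygote) / len(recs)


def expected_heterozygosity_unbiased(f: FrequencyTable) -> float:
    """Unbiased expected heterozygosity (2N/(2N-1)) (1 - sum p_i^2)."""
    copies = 2 * f.n_individuals
    gene_diversity = 1.0 - sum(a.p ** 2 for a in f.alleles.values())
    return copies / (copies - 1) * gene_diversity


def _pair_copies(copies: np.ndarray) -> float:
    """Observed heterozygosity of genotypes formed by consecutive pairing."""
    a = copies[0::2]
    b = copies[1::2]
    return float(np.mean(a != b))


def _permutation_null(g: GenotypeTable, population: str, n_perm: int,
                      seed: int) -> tuple[float, float, np.ndarray]:
    """Observed h_o, fixed unbiased h_e, and permuted h_o values under the
    null that gene copies pair at random given the observed allele counts."""
    counts = g.allele_counts(population)
    if len(counts) < 2:
        raise ValidationError(f"population {population!r} is monomorphic")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    h_obs = observed_heterozygosity(g, population)
    h_exp = expected_heterozygosity_unbiased(allele_frequencies(g, population))
    codes = {name: i for i, name in enumerate(sorted(counts))}
    pool = np.repeat(
        np.array([codes[name] for name in sorted(counts)]),
        [counts[name] for name in sorted(counts)],
    )
    rng = np.random.default_rng(seed)
    perm_ho = np.empty(n_perm)
    for i in range(n_perm):
        rng.shuffle(pool)
        perm_ho[i] = _pair_copies(pool)
    return h_obs, h_exp, perm_ho


def hwe_exact_test(g: GenotypeTable, population: str, n_perm: int = 10_000,
                   seed: int = 0) -> float:
    """One-sided Monte-Carlo exact test of heterozygote deficit.

    The statistic is F_IS of each re-paired table; since the permutation
    conditions on allele counts, h_e is fixed and F_IS >= observed is
    equivalent to permuted h_o <= observed.  The add-one estimator
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) never returns zero.
    """
    h_obs, _h_exp, perm_ho = _permutation_null(g, population, n_perm, seed)
    n_ge = int(np.sum(perm_ho <= h_obs + 1e-12))
    return (1 + n_ge) / (1 + n_perm)


def f_is(g: GenotypeTable, population: str, n_perm: int = 10_000,
         seed: int = 0) -> tuple[float, float]:
    """F_IS = 1 - h_o/h_e and its one-sided heterozygote-deficit p-value.

    The p-value comes from the same Monte-Carlo permutation null as
    :func:`hwe_exact_test` with F_IS as statistic, Pr(F_perm >= F_obs).
    """
    h_obs, h_exp, perm_ho = _permutation_null(g, population, n_perm, seed)
    fis = 1.0 - h_obs / h_exp
    n_ge = int(np.sum(1.0 - perm_ho / h_exp >= fis - 1e-12))
    return fis, (1 + n_ge) / (1 + n_perm)


def diversity_stats(g: GenotypeTable, population: str, n_perm: int = 10_000,
                    seed: int = 0) -> DiversityStats:
    """Assemble the per-population diversity summary block."""
    freqs = allele_frequencies(g, population)
    h_o = observed_heterozygosity(g, population)
    if freqs.n_alleles == 1:
        return DiversityStats(population, freqs.n_individuals, 1, 0.0, 0.0,
                              None, None, None)
    h_e = expected_heterozygosity_unbiased(freqs)
    fis, fis_p = f_is(g, population, n_perm=n_perm, seed=seed)
    hwe_p = hwe_exact_test(g, population, n_perm=n_perm, seed=seed)
    return DiversityStats(population, freqs.n_individuals, freqs.n_alleles,
                          h_o, h_e, fis, fis_p, hwe_p)


def size_effect_correlation(stats: list[DiversityStats], field: str) -> float:
    """Pearson correlation between sample size N and h_o or h_e, used to
    check that the heterozygosity estimates are not driven by sample size."""
    if field not in ("h_o", "h_e"):
        raise ValidationError(f"field must be 'h_o' or 'h_e', got {field!r}")
    if len(stats) < 3:
        raise ValidationError("need at least 3 populations")
    n = np.array([s.n for s in stats], dtype=float)
    y = np.array([getattr(s, field) for s in stats], dtype=float)
    if np.var(y) == 0 or np.var(n) == 0:
        raise ValidationError("correlation undefined: zero variance")
    return float(np.corrcoef(n, y)[0, 1])
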