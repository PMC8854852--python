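"""Rarefaction allelic richness.

The raw allele count N_a grows with sample size, so populations typed at
different depths are compared through allelic richness R_s: the expected
number of distinct alleles in a standardized subsample of g gene copies,
computed by hypergeometric rarefaction

    R_s(g) = sum_i [ 1 - C(2N - c_i, g) / C(2N, g) ]

where c_i is the copy count of allele i.  Binomial coefficients are
evaluated in log space, so large cohorts pose no overflow problem.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.special import gammaln

from .io_model import FrequencyTable, ValidationError

__all__ = ["RarefactionResult", "rarefied_richness", "standardize_g"]


@dataclass(frozen=True)
class RarefactionResult:
    population: str
    g: int
    r_s: float


def _log_choose(a: int, b: int) -> float:
    return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))


def rarefied_richness(f: FrequencyTable, g: int) -> RarefactionResult:
    """Expected number of distinct alleles among g gene copies drawn
    without replacement from the population sample."""
    copies = 2 * f.n_individuals
    if not 2 <= g <= copies:
        raise ValidationError(f"g must lie in [2, {copies}], got {g}")
    log_denom = _log_choose(copies, g)
    r_s = 0.0
    for a in f.alleles.values():
        if a.count == 0:
            continue
        remaining = copies - a.count
        if remaining < g:
            # cannot form a subsample missing this allele
            r_s += 1.0
        else:
            import math
            r_s += 1.0 - math.exp(_log_choose(remaining, g) - log_denom)
    return RarefactionResult(population=f.population, g=g, r_s=r_s)


def standardize_g(tables: list[FrequencyTable]) -> int:
    """The largest standardized sample size valid for every population:
    twice the smallest N."""
    if not tables:
        raise ValidationError("need at least one frequency table")
    return 2 * min(t.n_individuals for t in tables)
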