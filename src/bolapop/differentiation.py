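"""Population differentiation: Weir-Cockerham F_ST, Nei D_A and PCA.

F_ST is estimated by the Weir-Cockerham variance-component estimator theta
applied to genotype data for a pair of populations, with significance from
permutation of individuals between the two populations.  Negative theta
estimates are reported as computed, not truncated at zero.  Nei's D_A
distance 1 - sum sqrt(x_i y_i) is computed from allele-frequency vectors,
and population structure is summarized by a covariance-based principal
component analysis of the populations-by-alleles frequency matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .allele_stats import allele_frequencies
from .io_model import (
    FrequencyTable,
    GenotypeRecord,
    GenotypeTable,
    PairwiseMatrix,
    ValidationError,
)

__all__ = [
    "PCAResult",
    "weir_cockerham_theta",
    "pairwise_fst",
    "nei_da",
    "frequency_pca",
    "distance_matrix",
]


@dataclass
class PCAResult:
    labels: list[str]
    scores: np.ndarray          # populations x components
    variance_explained: np.ndarray  # percentages, descending
    loadings: np.ndarray        # components x alleles
    allele_order: list[str]


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def _encode(recs_by_pop: list[list[GenotypeRecord]]) -> tuple[list[np.ndarray], list[np.ndarray], int]:
    alleles = sorted({al for recs in recs_by_pop for rec in recs
                      for al in (rec.allele_a, rec.allele_b)})
    code = {al: i for i, al in enumerate(alleles)}
    a_codes = [np.array([code[r.allele_a] for r in recs]) for recs in recs_by_pop]
    b_codes = [np.array([code[r.allele_b] for r in recs]) for recs in recs_by_pop]
    return a_codes, b_codes, len(alleles)


def _theta_components_coded(a_codes: list[np.ndarray], b_codes: list[np.ndarray],
                            n_alleles: int) -> tuple[float, float]:
    """Sums over alleles of the a and (a+b+c) variance components for r
    populations given integer-coded genotype arrays."""
    r = len(a_codes)
    sizes = np.array([len(a) for a in a_codes], dtype=float)
    n_bar = sizes.mean()
    n_c = (r * n_bar - np.sum(sizes ** 2) / (r * n_bar)) / (r - 1)
    # p[k, i]: frequency of allele k in population i; h[k, i]: observed
    # frequency of heterozygotes carrying allele k
    p = np.empty((n_alleles, r))
    h = np.empty((n_alleles, r))
    for i, (a, b) in enumerate(zip(a_codes, b_codes)):
        n_i = len(a)
        p[:, i] = np.bincount(np.concatenate([a, b]), minlength=n_alleles) / (2 * n_i)
        het = a != b
        h[:, i] = (
            np.bincount(a[het], minlength=n_alleles)
            + np.bincount(b[het], minlength=n_alleles)
        ) / n_i
    p_bar = (p * sizes).sum(axis=1) / (r * n_bar)
    s2 = ((p - p_bar[:, None]) ** 2 * sizes).sum(axis=1) / ((r - 1) * n_bar)
    h_bar = (h * sizes).sum(axis=1) / (r * n_bar)
    inner = p_bar * (1 - p_bar) - ((r - 1) / r) * s2
    a_comp = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1))
    b_comp = (n_bar / (n_bar - 1)) * (inner - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar)
    c_comp = h_bar / 2.0
    return float(a_comp.sum()), float((a_comp + b_comp + c_comp).sum())


def _theta_components(recs_by_pop: list[list[GenotypeRecord]]) -> tuple[float, float]:
    a_codes, b_codes, n_alleles = _encode(recs_by_pop)
    if n_alleles < 2:
        raise ValidationError("theta undefined: populations are jointly monomorphic")
    return _theta_components_coded(a_codes, b_codes, n_alleles)


def weir_cockerham_theta(g: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Point estimate of theta (F_ST) for two populations."""
    recs = [g.population_records(pop_a), g.population_records(pop_b)]
    sum_a, sum_abc = _theta_components(recs)
    if sum_abc == 0:
        raise ValidationError("theta undefined: zero total variance")
    return sum_a / sum_abc


def pairwise_fst(g: GenotypeTable, pop_a: str, pop_b: str, n_perm: int = 1000,
                 seed: int = 0) -> tuple[float, float]:
    """Theta with a permutation p-value.

    The null distribution is generated by shuffling individuals between the
    two populations (sample sizes preserved); p uses the add-one estimator
    Pr(theta_perm >= theta_obs).
    """
    recs_a = g.population_records(pop_a)
    recs_b = g.population_records(pop_b)
    theta = weir_cockerham_theta(g, pop_a, pop_b)
    a_codes, b_codes, n_alleles = _encode([recs_a, recs_b])
    all_a = np.concatenate(a_codes)
    all_b = np.concatenate(b_codes)
    n_a = len(recs_a)
    rng = np.random.default_rng(seed)
    idx = np.arange(len(all_a))
    n_ge = 0
    for _ in range(n_perm):
        rng.shuffle(idx)
        ia, ib = idx[:n_a], idx[n_a:]
        sum_a, sum_abc = _theta_components_coded(
            [all_a[ia], all_a[ib]], [all_b[ia], all_b[ib]], n_alleles
        )
        t = sum_a / sum_abc if sum_abc != 0 else 0.0
        if t >= theta - 1e-12:
            n_ge += 1
    return theta, (1 + n_ge) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Nei D_A and PCA
# ---------------------------------------------------------------------------


def nei_da(fa: FrequencyTable, fb: FrequencyTable) -> float:
    """Nei's D_A = 1 - sum_i sqrt(x_i y_i) over the union of alleles."""
    union = set(fa.alleles) | set(fb.alleles)
    xa = {k: v.p for k, v in fa.alleles.items()}
    xb = {k: v.p for k, v in fb.alleles.items()}
    s = sum(np.sqrt(xa.get(k, 0.0) * xb.get(k, 0.0)) for k in union)
    return float(1.0 - s)


def frequency_pca(tables: list[FrequencyTable], n_components: int = 2) -> PCAResult:
    """PCA of the populations-by-alleles frequency matrix.

    Columns (alleles) are mean-centered; the decomposition is of the
    covariance, not the correlation, since all columns share the frequency
    scale.  Components are ordered by decreasing variance and signed so the
    first nonzero loading of each component is positive.
    """
    if len(tables) < 3:
        raise ValidationError("PCA needs at least 3 populations")
    allele_order = sorted({a for t in tables for a in t.alleles})
    X = np.vstack([t.frequency_vector(allele_order) for t in tables])
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    s = np.where(s > 1e-10, s, 0.0)  # identical populations: flag degenerate
    rank = int(np.sum(s > 0))
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; "
            "truncating" + (" (degenerate input)" if rank == 0 else ""),
            stacklevel=2,
        )
        n_components = max(rank, 1)
    eigvals = s ** 2 / (len(tables) - 1)
    total = eigvals.sum()
    var_pct = (eigvals / total * 100.0) if total > 0 else np.zeros_like(eigvals)
    scores = u * s
    loadings = vt
    for j in range(n_components):
        nz = np.nonzero(np.abs(loadings[j]) > 1e-12)[0]
        if nz.size and loadings[j, nz[0]] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        labels=[t.population for t in tables],
        scores=scores[:, :n_components],
        variance_explained=var_pct[:n_components],
        loadings=loadings[:n_components],
        allele_order=allele_order,
    )


def distance_matrix(g: GenotypeTable, method: str, n_perm: int = 1000,
                    seed: int = 0) -> PairwiseMatrix:
    """Symmetric matrix of pairwise theta (with permutation p-values) or
    Nei D_A over all populations of a genotype table."""
    pops = g.populations()
    if len(pops) < 2:
        raise ValidationError("need at least 2 populations")
    k = len(pops)
    values = np.zeros((k, k))
    p_values = np.ones((k, k)) if method == "fst" else None
    freqs = {p: allele_frequencies(g, p) for p in pops}
    for i in range(k):
        for j in range(i + 1, k):
            if method == "fst":
                theta, p = pairwise_fst(g, pops[i], pops[j], n_perm=n_perm,
                                        seed=seed + 1000 * i + j)
                values[i, j] = values[j, i] = theta
                p_values[i, j] = p_values[j, i] = p
            elif method == "da":
                values[i, j] = values[j, i] = nei_da(freqs[pops[i]], freqs[pops[j]])
            else:
                raise ValidationError(f"unknown method {method!r}")
    return PairwiseMatrix(labels=pops, values=values, kind=method, p_values=p_values)
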