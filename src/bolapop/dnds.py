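"""Pairwise Nei-Gojobori dN/dS with Jukes-Cantor correction and Z-test.

Each codon contributes fractional synonymous site counts: for every
position, the fraction of the three possible single-base changes that
preserve the amino acid (changes to stop codons count as nonsynonymous).
Differences between two codons are classified by enumerating every minimal
substitution pathway (all orderings of the differing positions), weighting
valid pathways equally; pathways that pass through a stop codon get zero
weight and the rest are renormalized.  Proportions p_S = S_d/S and
p_N = N_d/N are corrected for multiple hits with the Jukes-Cantor transform
d = -(3/4) ln(1 - 4p/3), which is undefined (saturated) at p >= 3/4.

Population-level averages are taken over all unordered pairs of distinct
alleles observed in the population (optionally weighted by allele
frequency), and positive selection (dN > dS) is assessed with a Z-test
whose variances come from bootstrap resampling of codon sites.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy.stats import norm

from .allele_stats import allele_frequencies
from .io_model import (
    AlleleSequenceSet,
    CODON_TO_AA,
    GenotypeTable,
    ValidationError,
)

__all__ = [
    "DnDsResult",
    "SaturationError",
    "codon_sites",
    "pathway_counts",
    "pairwise_dnds",
    "population_dnds",
    "jukes_cantor",
]

_BASES = "ACGT"


class SaturationError(ValidationError):
    """Jukes-Cantor correction undefined: proportion of differences >= 3/4."""


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of a sense codon.

    Summed over the three positions, each contributing the fraction of its
    three possible changes that are synonymous; the two counts add to 3.
    """
    if codon not in CODON_TO_AA:
        raise ValidationError(f"not a sense codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for i in range(3):
        syn_changes = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if CODON_TO_AA.get(alt) == aa:
                syn_changes += 1
        syn += syn_changes / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(S_d, N_d): synonymous and nonsynonymous difference counts between
    two sense codons, averaged over all valid minimal substitution
    pathways with equal weights."""
    for c in (codon_a, codon_b):
        if c not in CODON_TO_AA:
            raise ValidationError(f"not a sense codon: {c!r}")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    path_sd: list[float] = []
    path_nd: list[float] = []
    for order in permutations(diff):
        current = codon_a
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt not in CODON_TO_AA:  # pathway crosses a stop codon
                valid = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if valid:
            path_sd.append(sd)
            path_nd.append(nd)
    if not path_sd:
        raise ValidationError(
            f"no stop-free substitution pathway between {codon_a} and {codon_b}"
        )
    return float(np.mean(path_sd)), float(np.mean(path_nd))


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4; distance saturated")
    if p <= 0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _split_codons(seq: str) -> list[str]:
    if len(seq) % 3 != 0:
        raise ValidationError(f"sequence length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _per_codon_arrays(codons_a: list[str], codons_b: list[str]) -> np.ndarray:
    """Per-codon array with rows (mean syn sites, S_d, N_d), shape (3, L)."""
    if len(codons_a) != len(codons_b):
        raise ValidationError("sequences differ in codon length")
    out = np.empty((3, len(codons_a)))
    for i, (ca, cb) in enumerate(zip(codons_a, codons_b)):
        sa, _ = codon_sites(ca)
        sb, _ = codon_sites(cb)
        sd, nd = pathway_counts(ca, cb)
        out[:, i] = ((sa + sb) / 2.0, sd, nd)
    return out


def _distances(arr: np.ndarray) -> tuple[float, float]:
    """(d_n, d_s) from an aggregated per-codon array (possibly resampled)."""
    s_sites = float(arr[0].sum())
    n_sites = 3.0 * arr.shape[1] - s_sites
    p_s = arr[1].sum() / s_sites if s_sites > 0 else 0.0
    p_n = arr[2].sum() / n_sites if n_sites > 0 else 0.0
    return jukes_cantor(p_n), jukes_cantor(p_s)


def pairwise_dnds(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Nei-Gojobori (d_n, d_s) between two codon-aligned sequences."""
    return _distances(_per_codon_arrays(_split_codons(seq_a), _split_codons(seq_b)))


@dataclass(frozen=True)
class DnDsResult:
    population: str
    d_n: float
    d_s: float
    ratio: float | None
    z: float
    p: float
    n_pairs: int
    n_excluded: int


def population_dnds(
    g: GenotypeTable,
    seqs: AlleleSequenceSet,
    population: str,
    n_boot: int = 1000,
    seed: int = 0,
    weighting: str = "unique",
) -> DnDsResult:
    """Mean pairwise d_n and d_s over the alleles observed in a population,
    with a one-tailed Z-test for the positive-selection alternative
    d_n > d_s.

    ``weighting='unique'`` (default) averages each unordered pair of
    distinct observed alleles once; ``weighting='frequency'`` weights pair
    (i, j) by the product of the two allele frequencies, so common alleles
    dominate the average.  Variances of the two means come from ``n_boot``
    bootstrap resamples of codon sites (shared indices across all pairs).
    """
    if weighting not in ("unique", "frequency"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    freqs = allele_frequencies(g, population)
    observed = sorted(a for a, rec in freqs.alleles.items() if rec.count > 0)
    if len(observed) < 2:
        raise ValidationError(f"population {population!r} has < 2 distinct alleles")
    missing = [a for a in observed if a not in seqs.sequences]
    if missing:
        raise ValidationError(f"no sequence for allele(s) {missing}")
    pairs = [(a, b) for i, a in enumerate(observed) for b in observed[i + 1 :]]
    arrays = []
    weights = []
    n_excluded = 0
    for a, b in pairs:
        arr = _per_codon_arrays(seqs.codons(a), seqs.codons(b))
        try:
            _distances(arr)
        except SaturationError:
            warnings.warn(f"pair ({a}, {b}) saturated; excluded", stacklevel=2)
            n_excluded += 1
            continue
        arrays.append(arr)
        if weighting == "frequency":
            weights.append(freqs.alleles[a].p * freqs.alleles[b].p)
        else:
            weights.append(1.0)
    if not arrays:
        raise ValidationError(f"all allele pairs saturated in {population!r}")
    w = np.asarray(weights) / np.sum(weights)

    def mean_dnds(idx: np.ndarray | None) -> tuple[float, float]:
        dn_vals = np.empty(len(arrays))
        ds_vals = np.empty(len(arrays))
        for k, arr in enumerate(arrays):
            sub = arr if idx is None else arr[:, idx]
            try:
                dn_vals[k], ds_vals[k] = _distances(sub)
            except SaturationError:
                dn_vals[k] = ds_vals[k] = np.nan
        ok = ~np.isnan(dn_vals)
        ww = w[ok] / w[ok].sum()
        return float(np.sum(ww * dn_vals[ok])), float(np.sum(ww * ds_vals[ok]))

    d_n, d_s = mean_dnds(None)
    rng = np.random.default_rng(seed)
    L = arrays[0].shape[1]
    boot_dn = np.empty(n_boot)
    boot_ds = np.empty(n_boot)
    for b_i in range(n_boot):
        idx = rng.integers(0, L, size=L)
        boot_dn[b_i], boot_ds[b_i] = mean_dnds(idx)
    var_total = float(np.var(boot_dn, ddof=1) + np.var(boot_ds, ddof=1))
    if var_total > 0:
        z = (d_n - d_s) / math.sqrt(var_total)
        p = float(norm.sf(z))
    else:
        z, p = (math.inf if d_n > d_s else 0.0), (0.0 if d_n > d_s else 1.0)
    ratio = d_n / d_s if d_s > 0 else None
    return DnDsResult(population, d_n, d_s, ratio, z, p,
                      n_pairs=len(arrays), n_excluded=n_excluded)
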