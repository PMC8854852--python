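"""Peptide-binding-region (PBR) repertoire comparison.

Within-population sequence diversity is summarized by pairwise identity and
BLOSUM62 similarity percentages over either the whole beta-1 domain or the
PBR positions only.  In the default ``copies`` mode every one of the 2N
allele copies carried by a population enters the pair set, so a pair formed
by an individual's two identical copies scores 100/100 and high
homozygosity raises the within-population identity, as it should for a
repertoire-size argument.  A ``unique`` mode restricting to distinct
alleles is also available.

Between populations, each population is represented by a positions-by-20
amino-acid frequency matrix over the PBR (the numeric content of a sequence
logo); flattened row-major into a vector (31 positions x 20 residues = 620
coordinates for the full PBR), vectors are compared by Pearson correlation,
either globally or restricted to the positions of one binding pocket, and
populations are clustered by UPGMA on d = 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .allele_stats import allele_frequencies
from .io_model import (
    AMINO_ACIDS,
    AlleleSequenceSet,
    GenotypeTable,
    PBRMask,
    PairwiseMatrix,
    ValidationError,
    blosum62_score,
)

__all__ = [
    "PBRProfile",
    "SimilaritySummary",
    "pair_identity_similarity",
    "population_similarity",
    "pbr_profile",
    "profile_correlation",
    "upgma",
]


@dataclass(frozen=True)
class SimilaritySummary:
    population: str
    region: str  # "beta1" or "pbr"
    identity_mean: float
    identity_sd: float
    similarity_mean: float
    similarity_sd: float

    def __post_init__(self):
        if not 0 <= self.identity_mean <= self.similarity_mean <= 100:
            raise ValidationError("need 0 <= identity <= similarity <= 100")


@dataclass
class PBRProfile:
    """Per-population amino-acid frequency matrix over masked positions."""

    population: str
    mask: PBRMask
    matrix: np.ndarray  # |mask| x 20, row-stochastic
    weighting: str      # "allele_unweighted" or "frequency_weighted"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.mask), len(AMINO_ACIDS)):
            raise ValidationError("profile matrix shape mismatch")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("profile rows must each sum to 1")

    @property
    def vector(self) -> np.ndarray:
        """Row-major flattening: positions ascending, residues A..Y."""
        return self.matrix.reshape(-1)

    def pocket_vector(self, pocket: str) -> np.ndarray:
        if pocket not in self.mask.pockets:
            raise ValidationError(f"unknown pocket {pocket!r}")
        rows = [self.mask.positions.index(p) for p in self.mask.pockets[pocket]]
        return self.matrix[rows].reshape(-1)


def pair_identity_similarity(
    pep_a: str, pep_b: str, positions: list[int] | None = None
) -> tuple[float, float]:
    """Identity and BLOSUM62 similarity percentages between two peptides.

    ``positions`` are 0-based indices into the peptides (default: all).
    A residue pair counts as similar when identical or when its BLOSUM62
    score is positive.
    """
    if len(pep_a) != len(pep_b):
        raise ValidationError("peptides differ in length")
    idx = range(len(pep_a)) if positions is None else positions
    idx = list(idx)
    if not idx:
        raise ValidationError("empty position set")
    ident = simil = 0
    for i in idx:
        a, b = pep_a[i], pep_b[i]
        if a == b:
            ident += 1
            simil += 1
        elif blosum62_score(a, b) > 0:
            simil += 1
    return 100.0 * ident / len(idx), 100.0 * simil / len(idx)


def _region_indices(seqs: AlleleSequenceSet, region: str, mask: PBRMask | None) -> list[int] | None:
    if region == "beta1":
        return None
    if region == "pbr":
        if mask is None:
            raise ValidationError("PBR region requires a mask")
        return [seqs.position_index(p) for p in mask.positions]
    raise ValidationError(f"unknown region {region!r}")


def population_similarity(
    g: GenotypeTable,
    seqs: AlleleSequenceSet,
    population: str,
    region: str = "beta1",
    mask: PBRMask | None = None,
    mode: str = "copies",
) -> SimilaritySummary:
    """Mean and SD of pairwise identity/similarity within a population.

    ``mode='copies'`` (default) scores all C(2N, 2) unordered pairs of the
    population's 2N allele copies, so pairs of identical copies contribute
    100/100; ``mode='unique'`` scores pairs of distinct observed alleles
    only.  SDs are population standard deviations (ddof=0) over the pair
    set.
    """
    if mode not in ("copies", "unique"):
        raise ValidationError(f"unknown mode {mode!r}")
    counts = g.allele_counts(population)
    missing = [a for a in counts if a not in seqs.sequences]
    if missing:
        raise ValidationError(f"no sequence for allele(s) {sorted(missing)}")
    positions = _region_indices(seqs, region, mask)
    observed = sorted(counts)
    # score distinct-allele pairs once, then expand by copy multiplicities
    vals: list[tuple[float, float]] = []
    weights: list[int] = []
    for i, a in enumerate(observed):
        for b in observed[i:]:
            if a == b:
                if mode == "unique":
                    continue
                w = counts[a] * (counts[a] - 1) // 2
                if w == 0:
                    continue
                vals.append((100.0, 100.0))
                weights.append(w)
            else:
                ident, simil = pair_identity_similarity(
                    seqs.peptides[a], seqs.peptides[b], positions
                )
                vals.append((ident, simil))
                weights.append(counts[a] * counts[b] if mode == "copies" else 1)
    if not vals:
        raise ValidationError(
            f"population {population!r} yields no allele pairs in mode {mode!r}"
        )
    arr = np.array(vals)
    w = np.array(weights, dtype=float)
    w /= w.sum()
    means = w @ arr
    sds = np.sqrt(w @ (arr - means) ** 2)
    return SimilaritySummary(population, region, means[0], sds[0], means[1], sds[1])


def pbr_profile(
    g: GenotypeTable,
    seqs: AlleleSequenceSet,
    population: str,
    mask: PBRMask,
    weighting: str = "allele_unweighted",
) -> PBRProfile:
    """Amino-acid frequency matrix over the masked positions for one
    population, over its distinct observed alleles (each counted once by
    default, or weighted by allele frequency)."""
    if weighting not in ("allele_unweighted", "frequency_weighted"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    freqs = allele_frequencies(g, population)
    observed = sorted(a for a, rec in freqs.alleles.items() if rec.count > 0)
    missing = [a for a in observed if a not in seqs.sequences]
    if missing:
        raise ValidationError(f"no sequence for allele(s) {missing}")
    aa_col = {aa: j for j, aa in enumerate(AMINO_ACIDS)}
    matrix = np.zeros((len(mask), len(AMINO_ACIDS)))
    if weighting == "allele_unweighted":
        w = {a: 1.0 / len(observed) for a in observed}
    else:
        w = {a: freqs.alleles[a].p for a in observed}
    for a in observed:
        pep = seqs.peptides[a]
        for row, pos in enumerate(mask.positions):
            matrix[row, aa_col[pep[seqs.position_index(pos)]]] += w[a]
    matrix /= matrix.sum(axis=1, keepdims=True)
    return PBRProfile(population, mask, matrix, weighting)


def profile_correlation(
    profiles: list[PBRProfile], pocket: str | None = None
) -> tuple[PairwiseMatrix, float]:
    """Pairwise Pearson correlation between flattened population profiles
    and the global summary (mean off-diagonal coefficient).

    With ``pocket`` given, vectors are restricted to that pocket's
    positions before correlating.
    """
    if len(profiles) < 2:
        raise ValidationError("need at least 2 profiles")
    mask0, w0 = profiles[0].mask, profiles[0].weighting
    for p in profiles[1:]:
        if p.mask != mask0 or p.weighting != w0:
            raise ValidationError("profiles must share mask and weighting")
    vectors = [
        p.vector if pocket is None else p.pocket_vector(pocket) for p in profiles
    ]
    for p, v in zip(profiles, vectors):
        if np.var(v) == 0:
            raise ValidationError(f"profile {p.population!r} has zero variance")
    k = len(profiles)
    values = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r = float(np.corrcoef(vectors[i], vectors[j])[0, 1])
            values[i, j] = values[j, i] = r
    matrix = PairwiseMatrix(
        labels=[p.population for p in profiles], values=values, kind="pcc"
    )
    return matrix, matrix.mean_offdiagonal()


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def upgma(matrix: PairwiseMatrix) -> str:
    """Size-weighted average-linkage (UPGMA) clustering; Newick output.

    Correlation matrices (kind ``pcc``) are first transformed to distances
    d = 1 - r.  The tree is ultrametric; ties are broken by lexicographic
    order of the smallest leaf label in each cluster, so the output is
    independent of input row order.
    """
    d = matrix.values.copy()
    if matrix.kind == "pcc":
        d = 1.0 - d
        np.fill_diagonal(d, 0.0)
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValidationError("distance matrix must have zero diagonal")
    def key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    # cluster state: (sort key = smallest leaf label, newick, size, height)
    order = sorted(range(len(matrix.labels)), key=lambda i: matrix.labels[i])
    clusters = [(matrix.labels[i], matrix.labels[i], 1, 0.0) for i in order]
    dist = {
        key(matrix.labels[i], matrix.labels[j]): float(d[i, j])
        for ii, i in enumerate(order)
        for j in order[ii + 1 :]
    }

    def get(a: str, b: str) -> float:
        return dist[key(a, b)]

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                cand = (get(clusters[i][0], clusters[j][0]),
                        clusters[i][0], clusters[j][0])
                if best is None or cand < best[0]:
                    best = (cand, i, j)
        (_dij, _, _), i, j = best
        ka, na, sa, ha = clusters[i]
        kb, nb, sb, hb = clusters[j]
        height = get(ka, kb) / 2.0
        newick = (
            f"({na}:{_fmt_len(height - ha)},{nb}:{_fmt_len(height - hb)})"
        )
        merged_key = min(ka, kb)
        merged = (merged_key, newick, sa + sb, height)
        others = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        for c in others:
            dnew = (sa * get(ka, c[0]) + sb * get(kb, c[0])) / (sa + sb)
            dist[key(merged_key, c[0])] = dnew
        clusters = sorted(others + [merged], key=lambda c: c[0])
    return clusters[0][1] + ";"
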