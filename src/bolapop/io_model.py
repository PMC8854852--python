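"""Domain types and file I/O for single-locus MHC genotype/sequence data.

The analyses in this package operate on three kinds of input:

* a genotype table listing, per individual, the population it belongs to and
  the two allele names carried at the locus (codominant typing of a single
  highly polymorphic locus such as BoLA-DRB3 exon 2);
* a set of codon-aligned nucleotide sequences, one per allele name, encoding
  the beta-1 domain of the class II beta chain;
* a peptide-binding-region (PBR) mask: the amino-acid positions whose side
  chains contact bound peptide, optionally partitioned into binding pockets.

All file formats are plain text (CSV/TSV and FASTA).  Writers emit a single
``#`` comment line recording the tool version and the parameters used.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "BolapopError",
    "ParseError",
    "ValidationError",
    "GenotypeRecord",
    "GenotypeTable",
    "AlleleSequenceSet",
    "AlleleFrequency",
    "FrequencyTable",
    "PBRMask",
    "PairwiseMatrix",
    "read_genotypes",
    "write_genotypes",
    "read_allele_fasta",
    "write_allele_fasta",
    "read_pbr_mask",
    "write_pbr_mask",
    "default_pbr_mask",
    "blosum62_score",
    "AMINO_ACIDS",
    "CODON_TO_AA",
    "SENSE_CODONS",
    "STOP_CODONS",
    "tsv_header_comment",
]

__version__ = "0.1.0"

GENOTYPE_COLUMNS = ("sample_id", "population", "allele1", "allele2")

#: the 20 standard amino acids in fixed alphabetical one-letter order; this
#: order defines the column order of every PBR profile matrix.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
CODON_TO_AA: Mapping[str, str] = dict(standard_dna_table.forward_table)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))


class BolapopError(Exception):
    """Base class for all package errors."""


class ParseError(BolapopError):
    """Malformed input file."""


class ValidationError(BolapopError):
    """Input violates a domain invariant."""


# ---------------------------------------------------------------------------
# BLOSUM62
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def _blosum62():
    return substitution_matrices.load("BLOSUM62")


def blosum62_score(a: str, b: str) -> int:
    """Return the BLOSUM62 substitution score for two standard amino acids.

    Raises :class:`ValidationError` for any residue outside the 20 standard
    amino acids (the matrix also carries B/Z/X/* columns, which are not
    meaningful for fully resolved allele sequences).
    """
    if a not in AMINO_ACIDS or b not in AMINO_ACIDS:
        raise ValidationError(f"unknown residue in pair ({a!r}, {b!r})")
    return int(_blosum62()[a, b])


# ---------------------------------------------------------------------------
# Genotype table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeRecord:
    sample_id: str
    population: str
    allele_a: str
    allele_b: str

    def __post_init__(self):
        for name, val in (
            ("sample_id", self.sample_id),
            ("population", self.population),
            ("allele_a", self.allele_a),
            ("allele_b", self.allele_b),
        ):
            if not val or not val.strip():
                raise ValidationError(f"empty {name} in record {self!r}")
        # allele order within an individual carries no information
        a, b = sorted((self.allele_a.strip(), self.allele_b.strip()))
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)
        object.__setattr__(self, "sample_id", self.sample_id.strip())
        object.__setattr__(self, "population", self.population.strip())

    @property
    def is_homozygote(self) -> bool:
        return self.allele_a == self.allele_b


@dataclass
class GenotypeTable:
    """Individuals with two named allele copies, grouped by population."""

    records: list[GenotypeRecord]

    def __post_init__(self):
        seen: set[str] = set()
        for rec in self.records:
            if rec.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {rec.sample_id!r}")
            seen.add(rec.sample_id)

    def populations(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.population not in out:
                out.append(rec.population)
        return out

    def population_records(self, population: str) -> list[GenotypeRecord]:
        recs = [r for r in self.records if r.population == population]
        if not recs:
            raise ValidationError(f"unknown population {population!r}")
        return recs

    def n(self, population: str) -> int:
        """Number of genotyped individuals N (gene copies = 2N)."""
        return len(self.population_records(population))

    def allele_counts(self, population: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.population_records(population):
            for allele in (rec.allele_a, rec.allele_b):
                counts[allele] = counts.get(allele, 0) + 1
        return counts

    def allele_names(self) -> list[str]:
        names: set[str] = set()
        for rec in self.records:
            names.add(rec.allele_a)
            names.add(rec.allele_b)
        return sorted(names)

    def subset(self, populations: Sequence[str]) -> "GenotypeTable":
        keep = set(populations)
        return GenotypeTable([r for r in self.records if r.population in keep])


def read_genotypes(path: str | Path, delimiter: str | None = None) -> GenotypeTable:
    """Read a genotype table from comma- or tab-delimited text.

    The header must name the four columns ``sample_id, population, allele1,
    allele2`` (any order).  The delimiter is sniffed from the header line when
    not given explicitly.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty genotype file")
    if delimiter is None:
        delimiter = "\t" if "\t" in lines[0] else ","
    reader = csv.reader(io.StringIO("\n".join(lines)), delimiter=delimiter)
    header = [h.strip() for h in next(reader)]
    missing = [c for c in GENOTYPE_COLUMNS if c not in header]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing} in header {header}")
    idx = {c: header.index(c) for c in GENOTYPE_COLUMNS}
    records: list[GenotypeRecord] = []
    for lineno, row in enumerate(reader, start=2):
        if not any(cell.strip() for cell in row):
            continue
        if len(row) < len(header):
            raise ParseError(f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}")
        try:
            records.append(
                GenotypeRecord(
                    sample_id=row[idx["sample_id"]],
                    population=row[idx["population"]],
                    allele_a=row[idx["allele1"]],
                    allele_b=row[idx["allele2"]],
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    try:
        return GenotypeTable(records)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def tsv_header_comment(**params) -> str:
    parts = [f"bolapop v{__version__}"] + [f"{k}={v}" for k, v in params.items()]
    return "# " + " ".join(parts)


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    """Serialize a genotype table as TSV (alleles written in sorted order)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(tsv_header_comment(format="genotypes") + "\n")
        fh.write("\t".join(GENOTYPE_COLUMNS) + "\n")
        for rec in table.records:
            fh.write(f"{rec.sample_id}\t{rec.population}\t{rec.allele_a}\t{rec.allele_b}\n")


# ---------------------------------------------------------------------------
# Allele sequences
# ---------------------------------------------------------------------------


@dataclass
class AlleleSequenceSet:
    """Codon-aligned nucleotide sequences keyed by allele name.

    ``translation_offset`` is the 1-based amino-acid number assigned to the
    first translated codon, so published domain numbering schemes can be
    reproduced regardless of where the alignment starts.
    """

    sequences: dict[str, str]
    translation_offset: int = 1
    peptides: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self):
        if not self.sequences:
            raise ValidationError("empty allele sequence set")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValidationError(f"sequences differ in length: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise ValidationError(f"sequence length {length} not divisible by 3")
        peptides: dict[str, str] = {}
        for name, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - set("ACGT")
            if bad:
                raise ValidationError(f"allele {name!r}: non-ACGT symbol(s) {sorted(bad)}")
            pep = str(Seq(seq).translate())
            if "*" in pep:
                raise ValidationError(f"allele {name!r}: translation contains a stop codon")
            self.sequences[name] = seq
            peptides[name] = pep
        self.peptides = peptides

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3

    def codons(self, allele: str) -> list[str]:
        seq = self.sequences[allele]
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]

    def position_index(self, aa_position: int) -> int:
        """Map a 1-based published amino-acid position to a 0-based index."""
        idx = aa_position - self.translation_offset
        if not 0 <= idx < self.n_codons:
            raise ValidationError(
                f"amino-acid position {aa_position} outside translated range "
                f"[{self.translation_offset}, {self.translation_offset + self.n_codons - 1}]"
            )
        return idx


def read_allele_fasta(path: str | Path, offset: int = 1) -> AlleleSequenceSet:
    """Read codon-aligned allele sequences from a nucleotide FASTA file."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id.strip()
        if name in sequences:
            raise ParseError(f"{path}: duplicate allele {name!r}")
        sequences[name] = str(rec.seq)
    if not sequences:
        raise ParseError(f"{path}: no FASTA records")
    return AlleleSequenceSet(sequences, translation_offset=offset)


def write_allele_fasta(seqs: AlleleSequenceSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name in sorted(seqs.sequences):
            fh.write(f">{name}\n{seqs.sequences[name]}\n")


# ---------------------------------------------------------------------------
# Frequency table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlleleFrequency:
    p: float
    se: float
    count: int


@dataclass
class FrequencyTable:
    """Per-population allele relative frequencies with ML standard errors."""

    population: str
    alleles: dict[str, AlleleFrequency]
    n_individuals: int

    def __post_init__(self):
        total_p = sum(a.p for a in self.alleles.values())
        if abs(total_p - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.population}: allele frequencies sum to {total_p}, not 1"
            )
        copies = 2 * self.n_individuals
        for name, a in self.alleles.items():
            if a.count > 0 and abs(a.p - a.count / copies) > 1e-9:
                raise ValidationError(f"{self.population}/{name}: p != count/2N")
            if a.se < 0:
                raise ValidationError(f"{self.population}/{name}: negative SE")

    @property
    def n_alleles(self) -> int:
        """Number of alleles observed at least once (N_a)."""
        return sum(1 for a in self.alleles.values() if a.count > 0)

    def frequency_vector(self, allele_order: Sequence[str]) -> np.ndarray:
        return np.array([self.alleles[a].p if a in self.alleles else 0.0 for a in allele_order])


# ---------------------------------------------------------------------------
# PBR mask
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PBRMask:
    """Ordered 1-based amino-acid positions forming the peptide-binding
    region, with optional pocket sub-assignments."""

    positions: tuple[int, ...]
    pockets: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.positions:
            raise ValidationError("empty PBR mask")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValidationError("mask positions must be strictly increasing and unique")
        pos = set(self.positions)
        for pocket, members in self.pockets.items():
            stray = set(members) - pos
            if stray:
                raise ValidationError(f"pocket {pocket!r} positions {sorted(stray)} not in mask")

    def __len__(self) -> int:
        return len(self.positions)


def read_pbr_mask(path: str | Path) -> PBRMask:
    """Read a mask from two-column delimited text (``position``, ``pocket``;
    pocket may be empty)."""
    path = Path(path)
    positions: list[int] = []
    pockets: dict[str, list[int]] = {}
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty mask file")
    delimiter = "\t" if "\t" in lines[0] else ","
    header = [h.strip() for h in lines[0].split(delimiter)]
    if header[0] != "position":
        raise ParseError(f"{path}: first column must be 'position', got {header}")
    for lineno, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split(delimiter)]
        try:
            pos = int(cells[0])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: bad position {cells[0]!r}") from exc
        positions.append(pos)
        if len(cells) > 1 and cells[1]:
            pockets.setdefault(cells[1], []).append(pos)
    return PBRMask(tuple(sorted(set(positions))), {k: tuple(v) for k, v in pockets.items()})


def write_pbr_mask(mask: PBRMask, path: str | Path) -> None:
    pocket_of = {p: k for k, members in mask.pockets.items() for p in members}
    with Path(path).open("w") as fh:
        fh.write(tsv_header_comment(format="pbr_mask") + "\n")
        fh.write("position\tpocket\n")
        for p in mask.positions:
            fh.write(f"{p}\t{pocket_of.get(p, '')}\n")


# Positions of the DRB beta-1 domain named as variable, invariable or under
# diversifying selection in published PBR analyses of this locus.  This set
# (28 positions) is an incomplete stand-in for the full 31-position MHC-DRB
# PBR definition; supply the complete mask to reproduce published
# 620-coordinate analyses exactly.
_DEFAULT_MASK_POSITIONS = (
    9, 10, 11, 12, 13, 14, 15, 26, 29, 30, 32, 37, 38, 40, 47, 57, 64, 67,
    70, 71, 72, 73, 74, 77, 78, 79, 82, 83,
)

# Pocket assignments follow the classical MHC-DRB pocket architecture
# (pockets P1, P4, P6, P7, P9 anchor peptide side chains), restricted to the
# default mask positions.  These are synthetic defaults for exploratory use;
# override via a mask file for a specific published pocket definition.
_DEFAULT_POCKETS = {
    "P1": (82, 83),
    "P4": (13, 70, 71, 74, 78),
    "P6": (11, 30),
    "P7": (47, 64, 67),
    "P9": (9, 37, 57),
}


def default_pbr_mask() -> PBRMask:
    """The package's default peptide-binding-region mask (28 positions)."""
    return PBRMask(_DEFAULT_MASK_POSITIONS, dict(_DEFAULT_POCKETS))


# ---------------------------------------------------------------------------
# Pairwise matrix
# ---------------------------------------------------------------------------

_MATRIX_KINDS = ("fst", "da", "pcc", "identity", "similarity")


@dataclass
class PairwiseMatrix:
    """Symmetric population-by-population matrix (distance or correlation)."""

    labels: list[str]
    values: np.ndarray
    kind: str
    p_values: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in _MATRIX_KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("matrix not symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def mean_offdiagonal(self, subset: Sequence[str] | None = None) -> float:
        """Mean of the off-diagonal entries, optionally over a named subset
        of populations (used for group-level differentiation summaries)."""
        idx = (
            list(range(len(self.labels)))
            if subset is None
            else [self.labels.index(s) for s in subset]
        )
        if len(idx) < 2:
            raise ValidationError("need at least two populations for an off-diagonal mean")
        vals = [self.values[i, j] for ii, i in enumerate(idx) for j in idx[ii + 1 :]]
        return float(np.mean(vals))

    def to_tsv(self, path: str | Path, **params) -> None:
        with Path(path).open("w") as fh:
            fh.write(tsv_header_comment(kind=self.kind, **params) + "\n")
            fh.write("population\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                fh.write(lab + "\t" + "\t".join(f"{v:.6g}" for v in self.values[i]) + "\n")
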