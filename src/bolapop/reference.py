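"""Embedded published benchmark tables.

Two small transcribed datasets ship with the package so that
frequency-level analyses can be exercised and cross-checked against
published values without access to raw genotypes:

* per-cohort diversity summaries (N, N_a, R_s, h_o, h_e, F_IS, dN, dS) for
  16 worldwide cattle populations typed at BoLA-DRB3;
* the relative frequencies of the 20 alleles shared by the Colombian
  Simbrah and Simmental cohorts.
"""

from __future__ import annotations

import csv
from importlib import resources

from .allele_stats import DiversityStats

__all__ = [
    "load_diversity_reference",
    "load_shared_allele_frequencies",
    "load_reference_dnds",
]


def _read_tsv(name: str) -> list[dict[str, str]]:
    path = resources.files("bolapop.data").joinpath(name)
    with path.open() as fh:
        rows = [ln for ln in fh if not ln.startswith("#")]
    return list(csv.DictReader(rows, delimiter="\t"))


def load_diversity_reference() -> list[DiversityStats]:
    """Published per-cohort diversity summaries as DiversityStats records
    (permutation p-values are not part of the transcription and are None)."""
    out = []
    for row in _read_tsv("diversity_reference.tsv"):
        out.append(
            DiversityStats(
                population=row["population"],
                n=int(row["n"]),
                n_a=int(row["n_a"]),
                h_o=float(row["h_o"]),
                h_e=float(row["h_e"]),
                f_is=float(row["f_is"]),
                f_is_p=None,
                hwe_p=None,
            )
        )
    return out


def load_reference_dnds() -> dict[str, tuple[float, float]]:
    """Published per-cohort mean pairwise (d_n, d_s)."""
    return {
        row["population"]: (float(row["d_n"]), float(row["d_s"]))
        for row in _read_tsv("diversity_reference.tsv")
    }


def load_shared_allele_frequencies() -> tuple[dict[str, float], dict[str, float], dict[str, int]]:
    """Frequencies of the alleles shared by the two Colombian cohorts.

    Returns (Simbrah frequencies, Simmental frequencies, cohort sizes).
    """
    sbh: dict[str, float] = {}
    smt: dict[str, float] = {}
    for row in _read_tsv("shared_allele_freqs.tsv"):
        sbh[row["allele"]] = float(row["SbhCo"])
        smt[row["allele"]] = float(row["SmtCo"])
    return sbh, smt, {"SbhCo": 60, "SmtCo": 67}
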