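"""End-to-end orchestration: one config in, a full report plus TSVs out.

A run either loads a genotype table / allele FASTA / PBR mask from disk or
simulates them, then executes every analysis stage in a fixed order:
allele frequencies, diversity and Hardy-Weinberg statistics, rarefaction
richness, pairwise F_ST and D_A, allele-frequency PCA, pairwise dN/dS with
the Z-test, within-population identity/similarity, PBR profiles with their
correlation matrix and UPGMA dendrogram.  Every stochastic stage derives
its own seed from the run seed, so reruns of the same config are
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .allele_stats import (
    allele_frequencies,
    diversity_stats,
    shared_allele_summary,
)
from .differentiation import distance_matrix, frequency_pca
from .dnds import population_dnds
from .io_model import (
    GenotypeTable,
    PBRMask,
    ValidationError,
    default_pbr_mask,
    read_allele_fasta,
    read_genotypes,
    read_pbr_mask,
    tsv_header_comment,
    write_allele_fasta,
    write_genotypes,
)
from .pbr import pbr_profile, population_similarity, profile_correlation, upgma
from .richness import rarefied_richness, standardize_g
from .simulate import SimulationConfig, simulate_allele_pool, simulate_metapopulation

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    Exactly one of (``genotypes_path`` + ``fasta_path``) or ``simulation``
    must be given.
    """

    genotypes_path: str | None = None
    fasta_path: str | None = None
    mask_path: str | None = None
    simulation: SimulationConfig | None = None
    n_perm: int = 1000
    n_boot: int = 200
    seed: int = 0
    g_override: int | None = None
    pbr_weighting: str = "allele_unweighted"
    similarity_mode: str = "copies"
    outdir: str = "bolapop_out"

    def __post_init__(self):
        have_paths = self.genotypes_path is not None and self.fasta_path is not None
        have_sim = self.simulation is not None
        if have_paths == have_sim:
            raise ValidationError(
                "exactly one of (genotypes_path + fasta_path) or simulation required"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        sim = data.pop("simulation", None)
        if sim is not None:
            if "pbr_mask" in sim:
                raise ValidationError("set the mask via mask_path, not the simulation block")
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **data)


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; write per-stage TSVs and ``report.json`` under
    ``cfg.outdir``; return the report as a dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask: PBRMask = read_pbr_mask(cfg.mask_path) if cfg.mask_path else default_pbr_mask()
    if cfg.simulation is not None:
        pool = simulate_allele_pool(cfg.simulation)
        genotypes: GenotypeTable = simulate_metapopulation(cfg.simulation, pool)
        write_genotypes(genotypes, outdir / "genotypes.tsv")
        write_allele_fasta(pool, outdir / "alleles.fasta")
    else:
        genotypes = read_genotypes(cfg.genotypes_path)
        pool = read_allele_fasta(cfg.fasta_path)
    pops = genotypes.populations()
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "n_boot": cfg.n_boot,
        "populations": pops,
    }

    # --- frequencies, diversity, richness -------------------------------
    freq_tables = {p: allele_frequencies(genotypes, p) for p in pops}
    for p in pops:
        ft = freq_tables[p]
        with (outdir / f"freqs_{p}.tsv").open("w") as fh:
            fh.write(tsv_header_comment(stage="freqs", population=p) + "\n")
            fh.write("allele\tcount\tp\tse\n")
            for name, a in sorted(ft.alleles.items()):
                fh.write(f"{name}\t{a.count}\t{a.p:.6g}\t{a.se:.6g}\n")
    g_std = cfg.g_override or standardize_g(list(freq_tables.values()))
    diversity = {}
    for p in pops:
        st = diversity_stats(genotypes, p, n_perm=cfg.n_perm, seed=cfg.seed)
        rr = rarefied_richness(freq_tables[p], g_std)
        diversity[p] = {
            "n": st.n, "n_a": st.n_a, "g": g_std, "r_s": _round(rr.r_s),
            "h_o": _round(st.h_o), "h_e": _round(st.h_e),
            "f_is": _round(st.f_is) if st.f_is is not None else None,
            "f_is_p": _round(st.f_is_p) if st.f_is_p is not None else None,
            "hwe_p": _round(st.hwe_p) if st.hwe_p is not None else None,
        }
    report["diversity"] = diversity
    with (outdir / "diversity.tsv").open("w") as fh:
        fh.write(tsv_header_comment(stage="diversity", n_perm=cfg.n_perm, seed=cfg.seed) + "\n")
        fh.write("population\tN\tN_a\tg\tR_s\th_o\th_e\tF_IS\tF_IS_p\thwe_p\n")
        for p in pops:
            d = diversity[p]
            fh.write(p + "\t" + "\t".join(str(d[k]) for k in
                     ("n", "n_a", "g", "r_s", "h_o", "h_e", "f_is", "f_is_p", "hwe_p")) + "\n")

    # --- shared alleles per pair ----------------------------------------
    shared = {}
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            names, mean_cum = shared_allele_summary(freq_tables[a], freq_tables[b])
            shared[f"{a}|{b}"] = {
                "n_shared": len(names),
                "mean_cumulative_frequency": _round(mean_cum),
            }
    report["shared_alleles"] = shared

    # --- differentiation -------------------------------------------------
    if len(pops) >= 2:
        fst = distance_matrix(genotypes, "fst", n_perm=cfg.n_perm, seed=cfg.seed)
        da = distance_matrix(genotypes, "da")
        fst.to_tsv(outdir / "fst.tsv", n_perm=cfg.n_perm, seed=cfg.seed)
        da.to_tsv(outdir / "da.tsv")
        report["fst"] = {
            "labels": fst.labels,
            "values": [[_round(v) for v in row] for row in fst.values.tolist()],
            "p_values": [[_round(v) for v in row] for row in fst.p_values.tolist()],
            "mean_offdiagonal": _round(fst.mean_offdiagonal()),
        }
        report["da"] = {
            "labels": da.labels,
            "values": [[_round(v) for v in row] for row in da.values.tolist()],
            "mean_offdiagonal": _round(da.mean_offdiagonal()),
        }
    if len(pops) >= 3:
        pca = frequency_pca(list(freq_tables.values()), n_components=2)
        report["pca"] = {
            "labels": pca.labels,
            "variance_explained": [_round(float(v)) for v in pca.variance_explained],
            "scores": [[_round(float(v)) for v in row] for row in pca.scores.tolist()],
        }
        with (outdir / "pca_scores.tsv").open("w") as fh:
            fh.write(tsv_header_comment(stage="pca") + "\n")
            fh.write("population\t" + "\t".join(
                f"PC{k+1}({v:.3g}%)" for k, v in enumerate(pca.variance_explained)) + "\n")
            for lab, row in zip(pca.labels, pca.scores):
                fh.write(lab + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    else:
        report["pca"] = None

    # --- selection -------------------------------------------------------
    sel = {}
    for p in pops:
        r = population_dnds(genotypes, pool, p, n_boot=cfg.n_boot, seed=cfg.seed)
        sel[p] = {
            "d_n": _round(r.d_n), "d_s": _round(r.d_s),
            "ratio": _round(r.ratio) if r.ratio is not None else None,
            "z": _round(r.z), "p": _round(r.p),
            "n_pairs": r.n_pairs, "n_excluded": r.n_excluded,
        }
    report["dnds"] = sel
    with (outdir / "dnds.tsv").open("w") as fh:
        fh.write(tsv_header_comment(stage="dnds", n_boot=cfg.n_boot, seed=cfg.seed) + "\n")
        fh.write("population\td_n\td_s\tratio\tz\tp\tn_pairs\tn_excluded\n")
        for p in pops:
            d = sel[p]
            fh.write(p + "\t" + "\t".join(str(d[k]) for k in
                     ("d_n", "d_s", "ratio", "z", "p", "n_pairs", "n_excluded")) + "\n")

    # --- PBR repertoire --------------------------------------------------
    sim_block = {}
    for p in pops:
        row = {}
        for region in ("beta1", "pbr"):
            s = population_similarity(genotypes, pool, p, region=region,
                                      mask=mask, mode=cfg.similarity_mode)
            row[region] = {
                "identity_mean": _round(s.identity_mean),
                "identity_sd": _round(s.identity_sd),
                "similarity_mean": _round(s.similarity_mean),
                "similarity_sd": _round(s.similarity_sd),
            }
        sim_block[p] = row
    report["similarity"] = sim_block

    profiles = [pbr_profile(genotypes, pool, p, mask, weighting=cfg.pbr_weighting)
                for p in pops]
    if len(pops) >= 2:
        try:
            pcc, global_pcc = profile_correlation(profiles)
            pcc.to_tsv(outdir / "pcc.tsv", weighting=cfg.pbr_weighting)
            newick = upgma(pcc)
            (outdir / "dendrogram.nwk").write_text(newick + "\n")
            pockets = {}
            for pocket in sorted(mask.pockets):
                _m, gp = profile_correlation(profiles, pocket=pocket)
                pockets[pocket] = _round(gp)
            report["pbr_correlation"] = {
                "labels": pcc.labels,
                "values": [[_round(v) for v in row] for row in pcc.values.tolist()],
                "global_pcc": _round(global_pcc),
                "pocket_global_pcc": pockets,
                "dendrogram": newick,
            }
        except ValidationError as exc:
            report["pbr_correlation"] = {"error": str(exc)}
    for prof, p in zip(profiles, pops):
        with (outdir / f"profile_{p}.tsv").open("w") as fh:
            fh.write(tsv_header_comment(stage="pbr_profile", population=p,
                                        weighting=cfg.pbr_weighting) + "\n")
            from .io_model import AMINO_ACIDS
            fh.write("position\t" + "\t".join(AMINO_ACIDS) + "\n")
            for pos, row in zip(mask.positions, prof.matrix):
                fh.write(str(pos) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
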