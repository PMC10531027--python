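"""End-to-end pipeline driver.

Orchestrates phenotype summary -> SNP QC -> per-population structure
(pruning, PCA, kinship) -> mixed-model GWAS -> permutation threshold ->
QTL calling -> cross-population co-location -> candidate-gene screening,
writing every artifact plus a manifest to an output directory. PCs and
kinship are recomputed within each population before its scan.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, candidates, gwas, io, qtl, structure
from .config import PipelineConfig
from .containers import GeneModel, GenotypeMatrix
from .phenotype import summarize_phenotype


def population_masks(phenotype: pd.DataFrame,
                     populations: tuple[str, ...]) -> dict[str, np.ndarray]:
    """Boolean accession mask per population tag.

    "Full" selects everyone; any other tag selects accessions whose subpop
    label starts with the tag, case-insensitively (so "Ind" matches
    "indica", "Jap" matches "japonica").
    """
    subpop = phenotype["subpop"].astype(str).str.lower().to_numpy()
    masks = {}
    for tag in populations:
        if tag.lower() == "full":
            masks[tag] = np.ones(len(phenotype), dtype=bool)
        else:
            masks[tag] = np.char.startswith(subpop.astype(str), tag.lower())
        if masks[tag].sum() == 0:
            raise ValueError(f"population {tag!r} matches no accessions")
    return masks


def run_population_scan(G: GenotypeMatrix, y: np.ndarray,
                        config: PipelineConfig, population: str,
                        seed: int) -> dict:
    """Structure + GWAS + threshold + QTLs for one population subset."""
    pruned_idx = structure.ld_prune(G, config.prune_window, config.prune_step,
                                    config.prune_r2)
    pca_res = structure.pca(G.take_snps(pruned_idx),
                            n_components=config.n_pcs) if config.n_pcs else None
    Q = pca_res.coordinates if pca_res is not None else None
    K = structure.kinship(G)
    null_fit = gwas.fit_null(y, Q, K)
    assoc = gwas.associate(G, y, Q, K, null_fit=null_fit,
                           min_maf=config.min_maf, population=population)
    thr = gwas.permutation_threshold(
        G, y, Q, K, n_perm=config.n_perm, quantile=config.quantile,
        seed=seed, min_maf=config.min_maf)
    sig = qtl.significant_snps(assoc, thr.threshold)
    qtls = qtl.call_qtls(sig, min_run=config.min_run, max_gap=config.max_gap,
                         population=population, trait=config.trait)
    return {"assoc": assoc, "threshold": thr, "sig": sig, "qtls": qtls,
            "pca": pca_res, "kinship": K, "null_fit": null_fit,
            "pruned_idx": pruned_idx}


def run_pipeline(config: PipelineConfig, outdir,
                 G: GenotypeMatrix | None = None,
                 phenotype: pd.DataFrame | None = None,
                 annotation: list[GeneModel] | None = None,
                 expression: pd.DataFrame | None = None) -> dict:
    """Execute the full pipeline; returns a results dict and writes artifacts.

    Inputs may be passed in memory or read from the paths in ``config``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_multi = 0
    if G is None:
        if config.genotypes_vcf is None:
            raise ValueError("no genotypes: pass G or set genotypes_vcf")
        G, n_multi = io.read_vcf(config.genotypes_vcf)
    if phenotype is None:
        if config.phenotype_tsv is None:
            raise ValueError("no phenotypes: pass table or set phenotype_tsv")
        phenotype = io.read_tsv(config.phenotype_tsv)
    if annotation is None and config.annotation_gff3 is not None:
        annotation = io.read_gff3(config.annotation_gff3)
    if expression is None and config.expression_tsv is not None:
        expression = io.read_tsv(config.expression_tsv)

    phenotype = (phenotype.set_index("accession")
                 .loc[G.accessions].reset_index())
    summary = summarize_phenotype(phenotype)
    io.write_json(asdict(summary) if hasattr(summary, "__dataclass_fields__")
                  else vars(summary), outdir / "phenotype_summary.json")

    Gq, qc = structure.filter_snps(G, config.max_missing, config.min_maf,
                                   n_removed_multiallelic=n_multi)
    io.write_tsv(pd.DataFrame([vars(qc)]), outdir / "qc_report.tsv")

    masks = population_masks(phenotype, config.populations)
    scans: dict[str, dict] = {}
    manifest_stages = []
    for k, (tag, mask) in enumerate(masks.items()):
        Gp = Gq.take_accessions(np.flatnonzero(mask))
        # re-QC within the subset: subpopulation MAF differs from panel MAF
        Gp, _ = structure.filter_snps(Gp, config.max_missing, config.min_maf)
        yp = phenotype.loc[mask, "mean_tfc"].to_numpy(dtype=float)
        scan = run_population_scan(Gp, yp, config, tag,
                                   seed=config.seed + 1000 + k)
        scans[tag] = scan
        scan["G"] = Gp
        scan["mask"] = mask
        io.write_tsv(scan["assoc"], outdir / f"assoc_{tag}.tsv")
        io.write_threshold(scan["threshold"], outdir / f"threshold_{tag}.json")
        io.write_tsv(qtl.qtl_table(scan["qtls"]), outdir / f"qtls_{tag}.tsv")
        manifest_stages.append({
            "population": tag, "n_accessions": int(mask.sum()),
            "n_snps": Gp.n_snps,
            "threshold": scan["threshold"].threshold,
            "n_qtls": len(scan["qtls"]),
        })

    sig_positions = {
        tag: {c: set(sub["pos"].astype(int))
              for c, sub in scan["sig"].groupby("chrom")}
        for tag, scan in scans.items()
    }
    tags = list(scans)
    coloc_all = []
    for i in range(len(tags)):
        for j in range(i + 1, len(tags)):
            a, b = tags[i], tags[j]
            coloc_all.extend(qtl.colocate(
                scans[a]["qtls"], scans[b]["qtls"], sig_positions,
                trait=config.trait))
    io.write_tsv(qtl.colocated_table(coloc_all), outdir / "colocated.tsv")

    reports = {}
    if annotation is not None and expression is not None:
        for cq in coloc_all:
            # screen with the member QTL carrying the stronger signal
            member = max((cq.qtl_a, cq.qtl_b),
                         key=lambda q: q.lead_neg_log10_p)
            scan = scans[member.population]
            sig_pos = scan["sig"].loc[
                scan["sig"]["chrom"] == member.chrom, "pos"
            ].to_numpy(dtype=np.int64)
            try:
                rep = candidates.screen_candidates(
                    member, scan["G"], sig_pos, annotation, expression,
                    phenotype.loc[scan["mask"]],
                    flank=config.flank, r2_min=config.r2_min,
                    promoter_len=config.promoter_len,
                    min_expr_class=config.min_expr_class,
                    min_group_n=config.min_group_n, alpha=config.alpha)
            except ValueError:
                continue
            reports[cq.name] = rep
            io.write_tsv(rep, outdir / f"candidates_{cq.name}.tsv")

    config.to_yaml(outdir / "config.yaml")
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "version": __version__,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "n_accessions": G.n_accessions,
        "n_snps_input": G.n_snps,
        "n_snps_qc": Gq.n_snps,
        "stages": manifest_stages,
        "n_colocated": len(coloc_all),
        "screened": sorted(reports),
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    io.write_json(manifest, outdir / "manifest.json")
    return {"genotypes": Gq, "qc": qc, "scans": scans,
            "colocated": coloc_all, "reports": reports,
            "summary": summary, "manifest": manifest}
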