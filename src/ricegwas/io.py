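"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF v4.2 (GT fields, 1-based POS, parsed with cyvcf2);
gene models as a compact GFF3 dialect (gene/mRNA/exon/UTR features with a
``gene_class`` attribute on the gene line, parsed with gffutils); tabular
artifacts as TSV with a header row and '.' for missing. GFF3 coordinates
stay 1-based inclusive; interval arithmetic elsewhere uses the
coordinate-difference length convention.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GeneModel, GenotypeMatrix

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write the dosage matrix as an uncompressed VCF v4.2 with GT fields."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(G.chrom.tolist()):  # preserve order
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.accessions) + "\n")
        for j in range(G.n_snps):
            calls = "\t".join(
                "./." if np.isnan(d) else _GT[d] for d in G.dosages[:, j])
            fh.write(f"{G.chrom[j]}\t{G.pos[j]}\t{G.chrom[j]}_{G.pos[j]}\t"
                     f"{G.ref[j]}\t{G.alt[j]}\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path) -> tuple[GenotypeMatrix, int]:
    """Parse a biallelic-SNP VCF into a GenotypeMatrix.

    Dosage is the alt-allele count; any missing allele makes the call
    missing. Rows with more than one ALT allele are dropped; their count is
    returned alongside the matrix so QC reports can include it.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        dos = np.empty(len(accessions))
        for i, g in enumerate(var.genotypes):
            a = g[:-1]  # final element is the phased flag
            if any(x < 0 for x in a):
                dos[i] = np.nan
            else:
                dos[i] = float(sum(1 for x in a if x > 0))
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(dos)
    vcf.close()
    if not rows:
        raise ValueError(f"no biallelic SNPs parsed from {path}")
    return GenotypeMatrix(
        accessions=accessions,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        dosages=np.vstack(rows).T,
    ), n_multi


def write_gff3(genes: list[GeneModel], path) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            gid = g.gene_id
            fh.write(f"{g.chrom}\tricegwas\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={gid};gene_class={g.gene_class}\n")
            mid = f"{gid}.1"
            fh.write(f"{g.chrom}\tricegwas\tmRNA\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={mid};Parent={gid}\n")
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tricegwas\texon\t{s}\t{e}\t.\t{g.strand}"
                         f"\t.\tID={mid}.exon{k};Parent={mid}\n")
            for k, (s, e) in enumerate(g.utr5, 1):
                fh.write(f"{g.chrom}\tricegwas\tfive_prime_UTR\t{s}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={mid}.utr5.{k};Parent={mid}\n")
            for k, (s, e) in enumerate(g.utr3, 1):
                fh.write(f"{g.chrom}\tricegwas\tthree_prime_UTR\t{s}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={mid}.utr3.{k};Parent={mid}\n")


def read_gff3(path) -> list[GeneModel]:
    """Parse gene models from GFF3 written by :func:`write_gff3`."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="error",
                            keep_order=True)
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        exons, utr5, utr3 = [], [], []
        for child in db.children(feat.id):
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
            if not (feat.start <= child.start <= child.end <= feat.end):
                raise ValueError(
                    f"feature {child.id} outside parent span of {feat.id}")
        genes.append(GeneModel(
            gene_id=feat.id, chrom=feat.seqid, strand=feat.strand,
            start=feat.start, end=feat.end,
            gene_class=feat.attributes.get("gene_class", ["gene"])[0],
            exons=sorted(exons), utr5=sorted(utr5), utr3=sorted(utr3)))
    return genes


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])


def write_kinship(K: np.ndarray, accessions: list[str], path) -> None:
    pd.DataFrame(K, index=accessions, columns=accessions).to_csv(
        path, sep="\t", index_label="accession")


def read_kinship(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


def write_threshold(result, path) -> None:
    payload = {
        "maxima": [float(x) for x in result.maxima],
        "quantile": result.quantile,
        "threshold": result.threshold,
        "n_perm": result.n_perm,
        "seed": result.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
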