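"""Candidate-gene screening funnel for a chosen QTL.

The funnel progressively narrows the gene pool: (1) delimit the local LD
interval around the lead SNP (the maximal run of significant SNPs with
r^2 >= 0.6 to the lead); (2) enumerate genes intersecting it; (3) drop
transposons / retrotransposons (and, by default, hypothetical proteins);
(4) keep genes with a significant SNP in the gene region — promoter, exon,
intron or UTR; (5) keep genes expressed in grain-related tissues (ovary,
embryo, endosperm); (6) keep genes whose haplotypes — accession groups
sharing the allele string over the gene's significant SNPs — differ
significantly in mean phenotype within a subpopulation (two-tailed
equal-variance t-test). Each gene records the first stage at which it fell
out.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneModel, GenotypeMatrix
from .qtl import QTL
from .structure import pairwise_r2

GRAIN_TISSUES = ("ovary", "embryo", "endosperm")

#: Expression-class cut points in linear units: below "none" the gene is
#: called unexpressed; classes are none < low < moderate < high.
DEFAULT_EXPR_CUTS = {"none": 1.0, "low": 5.0, "moderate": 20.0}

FUNNEL_STAGES = ("ld_interval", "transposon", "sig_snp", "expression",
                 "haplotype", "candidate")


@dataclass
class LdInterval:
    qtl_name: str
    chrom: str
    lead_pos: int
    member_pos: np.ndarray
    r2_to_lead: np.ndarray
    left: int
    right: int

    @property
    def length(self) -> int:
        return self.right - self.left

    @property
    def length_kb(self) -> int:
        """Length rounded to the nearest whole kb."""
        return int(np.floor(self.length / 1000.0 + 0.5))


@dataclass
class HaplotypeGroup:
    gene_id: str
    defining_pos: tuple[int, ...]
    allele_string: str
    accession_ids: list[str]
    subpop_stats: dict[str, tuple[int, float, float]]  # label -> (n, mean, sd)

    @property
    def n(self) -> int:
        return len(self.accession_ids)


@dataclass
class HaplotypeResult:
    gene_id: str
    groups: list[HaplotypeGroup]
    tests: pd.DataFrame  # subpop, hap_a, hap_b, n_a, n_b, t, p
    significant: bool  # any within-subpopulation pair with p < alpha
    alpha: float = 0.05


def local_ld_interval(qtl: QTL, G: GenotypeMatrix,
                      sig_positions: np.ndarray | None = None,
                      flank: int = 1_000_000, r2_min: float = 0.6,
                      max_interruptions: int = 0) -> LdInterval:
    """Local LD interval: consecutive significant SNPs linked to the lead.

    Significant SNPs within ``lead +/- flank`` are ordered by position and
    each one's r^2 to the lead computed; the interval spans the maximal run
    containing the lead in which every SNP has r^2 >= r2_min, allowing up
    to ``max_interruptions`` below-threshold SNPs inside the run (default
    none: the run breaks strictly).
    """
    pos = np.asarray(qtl.member_pos if sig_positions is None else sig_positions,
                     dtype=np.int64)
    pos = np.unique(pos)
    pos = pos[(pos >= qtl.lead_pos - flank) & (pos <= qtl.lead_pos + flank)]
    if qtl.lead_pos not in pos:
        raise ValueError("lead SNP not among the significant positions")
    lead_col = G.snp_index(qtl.chrom, qtl.lead_pos)
    if np.nanstd(G.dosages[:, lead_col]) == 0:
        raise ValueError("lead SNP is monomorphic; r^2 undefined")
    r2 = np.empty(pos.size)
    for k, p in enumerate(pos):
        if p == qtl.lead_pos:
            r2[k] = 1.0
        else:
            r2[k] = pairwise_r2(G, lead_col, G.snp_index(qtl.chrom, int(p)))
    linked = ~np.isnan(r2) & (r2 >= r2_min)
    li = int(np.flatnonzero(pos == qtl.lead_pos)[0])

    lo = li
    misses = 0
    k = li - 1
    while k >= 0:
        if linked[k]:
            lo = k
        else:
            misses += 1
            if misses > max_interruptions:
                break
        k -= 1
    hi = li
    misses = 0
    k = li + 1
    while k < pos.size:
        if linked[k]:
            hi = k
        else:
            misses += 1
            if misses > max_interruptions:
                break
        k += 1
    sel = slice(lo, hi + 1)
    return LdInterval(
        qtl_name=qtl.name, chrom=qtl.chrom, lead_pos=qtl.lead_pos,
        member_pos=pos[sel], r2_to_lead=r2[sel],
        left=int(pos[lo]), right=int(pos[hi]))


def genes_in_interval(genes: list[GeneModel], chrom: str,
                      interval: tuple[int, int]) -> list[GeneModel]:
    """Genes whose span has positive intersection with the interval.

    Uses the coordinate-difference convention: a gene merely abutting an
    endpoint (gene.end == interval.left) is excluded.
    """
    left, right = interval
    return [g for g in genes
            if g.chrom == str(chrom) and max(g.start, left) < min(g.end, right)]


def filter_transposons(genes: list[GeneModel],
                       exclude_hypothetical: bool = True) -> list[GeneModel]:
    """Drop transposons and retrotransposons (and hypotheticals by default)."""
    drop = {"transposon", "retrotransposon"}
    if exclude_hypothetical:
        drop.add("hypothetical")
    return [g for g in genes if g.gene_class not in drop]


def classify_snp_location(pos: int, gene: GeneModel,
                          promoter_len: int = 2000) -> str:
    """Region class of a SNP relative to a gene model.

    Returns one of promoter / exon / intron / 5'UTR / 3'UTR / outside. UTR
    stubs are recorded as sub-spans of terminal exons, so UTR membership is
    resolved before the surrounding exon; any other position inside the
    gene span is intronic. The promoter is the upstream window of
    ``promoter_len`` bp respecting strand.
    """
    if gene.start <= pos <= gene.end:
        for s, e in gene.utr5:
            if s <= pos <= e:
                return "5'UTR"
        for s, e in gene.utr3:
            if s <= pos <= e:
                return "3'UTR"
        for s, e in gene.exons:
            if s <= pos <= e:
                return "exon"
        return "intron"
    ps, pe = gene.promoter(promoter_len)
    if ps <= pos <= pe:
        return "promoter"
    return "outside"


def genes_with_significant_snps(genes: list[GeneModel],
                                sig_positions: np.ndarray,
                                promoter_len: int = 2000
                                ) -> dict[str, list[str]]:
    """Genes hit by >=1 significant SNP in their gene region.

    Returns gene_id -> sorted list of region classes hit (non-outside).
    """
    sig = np.asarray(sorted(set(int(p) for p in np.asarray(sig_positions))))
    hits: dict[str, list[str]] = {}
    for g in genes:
        ps, pe = g.promoter(promoter_len)
        lo = min(g.start, ps)
        hi = max(g.end, pe)
        near = sig[(sig >= lo) & (sig <= hi)]
        classes = {classify_snp_location(int(p), g, promoter_len) for p in near}
        classes.discard("outside")
        if classes:
            hits[g.gene_id] = sorted(classes)
    return hits


def expression_class(levels: np.ndarray,
                     cuts: dict[str, float] = DEFAULT_EXPR_CUTS) -> str:
    """Qualitative class of a gene from its grain-tissue expression levels."""
    if levels.size == 0:
        return "unmeasured"
    peak = float(np.nanmax(levels))
    if peak < cuts["none"]:
        return "none"
    if peak < cuts["low"]:
        return "low"
    if peak < cuts["moderate"]:
        return "moderate"
    return "high"


def expression_filter(genes: list[GeneModel], expr: pd.DataFrame,
                      tissues: tuple[str, ...] = GRAIN_TISSUES,
                      cuts: dict[str, float] = DEFAULT_EXPR_CUTS,
                      min_class: str = "moderate"
                      ) -> tuple[list[GeneModel], dict[str, str]]:
    """Keep genes expressed in grain-related tissues.

    ``min_class`` is the lowest retained class (default "moderate": genes
    with moderate or high peak expression survive; set "low" to keep weakly
    expressed genes too). Genes absent from the table are classed
    "unmeasured" and retained with a warning.
    """
    order = ["none", "low", "moderate", "high"]
    if min_class not in order:
        raise ValueError(f"min_class must be one of {order}")
    floor = order.index(min_class)
    grain = expr.loc[expr["tissue"].isin(tissues)]
    classes: dict[str, str] = {}
    kept: list[GeneModel] = []
    for g in genes:
        levels = grain.loc[grain["gene_id"] == g.gene_id, "level"].to_numpy()
        cls = expression_class(levels, cuts)
        classes[g.gene_id] = cls
        if cls == "unmeasured":
            warnings.warn(f"{g.gene_id} absent from expression table; retained",
                          stacklevel=2)
            kept.append(g)
        elif order.index(cls) >= floor:
            kept.append(g)
    return kept, classes


def haplotype_analysis(gene: GeneModel, sig_positions: np.ndarray,
                       G: GenotypeMatrix, phenotype: pd.DataFrame,
                       min_group_n: int = 10, alpha: float = 0.05,
                       promoter_len: int = 2000) -> HaplotypeResult:
    """Group accessions by allele string at the gene's significant SNPs.

    Only accessions with complete homozygous calls (dosage 0 or 2) at every
    defining SNP are grouped; groups smaller than ``min_group_n`` are
    dropped. Within each subpopulation holding >= 2 surviving groups, every
    group pair is compared by a two-sample, two-tailed, equal-variance
    Student's t-test on mean TFC; the gene is haplotype-significant if any
    pair has p < alpha.
    """
    ps, pe = gene.promoter(promoter_len)
    lo, hi = min(gene.start, ps), max(gene.end, pe)
    defining = [int(p) for p in sorted(set(int(x) for x in sig_positions))
                if lo <= p <= hi and
                classify_snp_location(int(p), gene, promoter_len) != "outside"]
    if not defining:
        raise ValueError(f"no significant SNPs in the region of {gene.gene_id}")
    cols = [G.snp_index(gene.chrom, p) for p in defining]
    D = G.dosages[:, cols]
    complete = np.all((D == 0.0) | (D == 2.0), axis=1)
    if not complete.any():
        raise ValueError("no haplotypes formable: no complete homozygous calls")

    pheno = phenotype.set_index("accession")
    strings: dict[str, list[int]] = {}
    for i in np.flatnonzero(complete):
        s = "".join("A" if d == 0.0 else "B" for d in D[i])
        strings.setdefault(s, []).append(i)

    # stable Hap numbering: larger groups first, ties by allele string
    ordered = sorted(strings.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    groups: list[HaplotypeGroup] = []
    values: dict[str, dict[str, np.ndarray]] = {}
    for s, idx in ordered:
        if len(idx) < min_group_n:
            continue
        ids = [G.accessions[i] for i in idx]
        sub_stats: dict[str, tuple[int, float, float]] = {}
        vals_by_sub: dict[str, np.ndarray] = {}
        rows = pheno.loc[[a for a in ids if a in pheno.index]]
        for sp, r in rows.groupby("subpop"):
            v = r["mean_tfc"].to_numpy(dtype=float)
            sub_stats[str(sp)] = (v.size, float(v.mean()),
                                  float(v.std(ddof=1)) if v.size > 1 else 0.0)
            vals_by_sub[str(sp)] = v
        name = f"Hap{len(groups) + 1}"
        groups.append(HaplotypeGroup(
            gene_id=gene.gene_id, defining_pos=tuple(defining),
            allele_string=s, accession_ids=ids, subpop_stats=sub_stats))
        values[name] = vals_by_sub

    rows = []
    names = [f"Hap{k + 1}" for k in range(len(groups))]
    subpops = sorted({sp for g in groups for sp in g.subpop_stats})
    for sp in subpops:
        present = [nm for nm in names if sp in values[nm]
                   and values[nm][sp].size >= 2]
        for a, b in itertools.combinations(present, 2):
            t, p = stats.ttest_ind(values[a][sp], values[b][sp],
                                   equal_var=True)
            rows.append({"subpop": sp, "hap_a": a, "hap_b": b,
                         "n_a": values[a][sp].size, "n_b": values[b][sp].size,
                         "t": float(t), "p": float(p)})
    tests = pd.DataFrame(rows, columns=["subpop", "hap_a", "hap_b",
                                        "n_a", "n_b", "t", "p"])
    significant = bool(len(tests) and (tests["p"] < alpha).any())
    return HaplotypeResult(gene_id=gene.gene_id, groups=groups, tests=tests,
                           significant=significant, alpha=alpha)


def screen_candidates(qtl: QTL, G: GenotypeMatrix, assoc_sig_pos: np.ndarray,
                      annotation: list[GeneModel], expr: pd.DataFrame,
                      phenotype: pd.DataFrame,
                      flank: int = 1_000_000, r2_min: float = 0.6,
                      promoter_len: int = 2000,
                      min_expr_class: str = "moderate",
                      min_group_n: int = 10, alpha: float = 0.05,
                      exclude_hypothetical: bool = True) -> pd.DataFrame:
    """Run the full funnel for one QTL; one report row per interval gene.

    Columns: gene_id, gene_class, in_ld_interval, non_te, has_sig_snp,
    snp_regions, expression_class, haplotype_p, first_fail, verdict.
    ``verdict`` is "candidate" for genes surviving every stage, else
    "excluded-at-<stage>".
    """
    interval = local_ld_interval(qtl, G, sig_positions=assoc_sig_pos,
                                 flank=flank, r2_min=r2_min)
    chrom_genes = [g for g in annotation if g.chrom == qtl.chrom]
    in_iv = genes_in_interval(chrom_genes, qtl.chrom,
                              (interval.left, interval.right))
    non_te = {g.gene_id for g in
              filter_transposons(in_iv, exclude_hypothetical)}
    sig_in_iv = np.asarray(
        [p for p in np.asarray(assoc_sig_pos, dtype=np.int64)
         if interval.left <= p <= interval.right])
    hit_map = genes_with_significant_snps(
        [g for g in in_iv if g.gene_id in non_te], sig_in_iv, promoter_len)
    expr_kept, expr_classes = expression_filter(
        [g for g in in_iv if g.gene_id in hit_map], expr,
        min_class=min_expr_class)
    expr_ids = {g.gene_id for g in expr_kept}

    rows = []
    for g in in_iv:
        row = {
            "gene_id": g.gene_id, "gene_class": g.gene_class,
            "in_ld_interval": True,
            "non_te": g.gene_id in non_te,
            "has_sig_snp": g.gene_id in hit_map,
            "snp_regions": ",".join(hit_map.get(g.gene_id, [])),
            "expression_class": expr_classes.get(g.gene_id, ""),
            "haplotype_p": np.nan,
            "first_fail": "", "verdict": "",
        }
        if g.gene_id not in non_te:
            row["first_fail"] = "transposon"
        elif g.gene_id not in hit_map:
            row["first_fail"] = "sig_snp"
        elif g.gene_id not in expr_ids:
            row["first_fail"] = "expression"
        else:
            try:
                hap = haplotype_analysis(g, sig_in_iv, G, phenotype,
                                         min_group_n=min_group_n, alpha=alpha,
                                         promoter_len=promoter_len)
                if len(hap.tests):
                    row["haplotype_p"] = float(hap.tests["p"].min())
                if not hap.significant:
                    row["first_fail"] = "haplotype"
            except ValueError:
                row["first_fail"] = "haplotype"
        row["verdict"] = ("candidate" if row["first_fail"] == ""
                          else f"excluded-at-{row['first_fail']}")
        rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["ld_interval"] = (interval.left, interval.right)
    report.attrs["qtl"] = qtl.name
    return report


def haplotype_utilization(result: HaplotypeResult, metadata: pd.DataFrame,
                          subpop: str | None = None) -> pd.DataFrame:
    """Haplotype proportions per breeding category, in whole percent.

    ``metadata`` columns: accession, improvement_status (landrace/improved)
    and optionally subpop for restriction. Proportion = members of the
    category carrying the haplotype / category size, rounded half away from
    zero; empty categories yield NaN with a warning.
    """
    meta = metadata.copy()
    if subpop is not None:
        meta = meta.loc[meta["subpop"] == subpop]
    hap_of: dict[str, str] = {}
    for k, g in enumerate(result.groups):
        for a in g.accession_ids:
            hap_of[a] = f"Hap{k + 1}"
    meta = meta.assign(haplotype=meta["accession"].map(hap_of))
    meta = meta.dropna(subset=["haplotype"])
    rows = []
    categories = sorted(metadata["improvement_status"].dropna().unique())
    haps = [f"Hap{k + 1}" for k in range(len(result.groups))]
    for cat in categories:
        members = meta.loc[meta["improvement_status"] == cat]
        n_cat = len(members)
        for h in haps:
            if n_cat == 0:
                warnings.warn(f"empty category {cat!r}; proportion undefined",
                              stacklevel=2)
                pct = np.nan
            else:
                frac = (members["haplotype"] == h).sum() / n_cat
                pct = float(np.floor(100.0 * frac + 0.5))
            rows.append({"haplotype": h, "category": cat,
                         "n_category": n_cat, "percent": pct})
    return pd.DataFrame(rows)
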