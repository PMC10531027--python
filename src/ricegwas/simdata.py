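"""Synthetic diversity-panel generator.

Emulates the statistical structure the downstream analysis assumes: a
two-subpopulation (indica/japonica-like) inbred rice panel with block-wise
linkage disequilibrium, planted causal SNPs of known effect size, a
polygenic background with covariance proportional to the realized kinship,
replicate phenotype measurements on a TFC-like scale (mg/100 g), and a toy
gene-annotation / tissue-expression layer. Every operation is deterministic
given the seed.

Genotypes follow a Balding-Nichols divergence model: an ancestral allele
frequency is drawn per SNP, then each subpopulation's frequency is drawn
from Beta(p(1-F)/F, (1-p)(1-F)/F) so that Hudson-estimator Fst over SNPs is
centred on the configured ``fst``. Frequencies are drawn per LD block (SNPs
on one haplotype block necessarily have similar frequencies) and linkage
disequilibrium comes from a haplotype-copying chain: each accession carries
a latent uniform per SNP, copied from the previous SNP with probability
exp(-d / ld_block_length) or drawn fresh, then thresholded at the
subpopulation allele frequency — marginal frequencies are exact and dosage
r^2 decays roughly as exp(-2d / ld_block_length).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, GeneModel
from .phenotype import DilutionScheme, StandardCurve
from .structure import kinship

GRAIN_TISSUES = ("ovary", "embryo", "endosperm")


@dataclass
class CausalSNP:
    """A planted causal variant: effect in phenotype units per allele copy."""

    chrom: str
    pos: int
    effect: float
    scope: str = "both"  # "both" or a subpopulation label


@dataclass
class SimConfig:
    n_accessions: int = 500
    subpop_fractions: tuple[float, ...] = (0.6, 0.4)
    subpop_labels: tuple[str, ...] = ("indica", "japonica")
    n_chromosomes: int = 3
    snps_per_chromosome: int = 2000
    chromosome_length: int = 20_000_000  # bp
    fst: float = 0.4
    ld_block_length: int = 150_000  # bp; decay scale of the copying chain
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    residual_het: float = 0.0
    causal_snps: list[CausalSNP] = field(default_factory=list)
    h2_qtl: float = 0.0
    h2_polygenic: float = 0.0
    baseline_tfc: float = 136.0  # mg/100 g, panel-typical mean
    base_sd: float = 38.0  # mg/100 g phenotypic SD when no QTL variance is set
    replicate_sd: float = 4.0  # field-replicate measurement noise, mg/100 g
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subpop_fractions) - 1.0) > 1e-12:
            raise ValueError("subpop_fractions must sum to 1")
        if any(not 0 <= f <= 1 for f in self.subpop_fractions):
            raise ValueError("subpop_fractions must lie in [0,1]")
        if len(self.subpop_labels) != len(self.subpop_fractions):
            raise ValueError("one label per subpopulation fraction required")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie strictly in (0,1)")
        if self.snps_per_chromosome <= 0 or self.n_chromosomes <= 0:
            raise ValueError("need at least one chromosome and one SNP")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0,1)")
        if not 0 <= self.h2_qtl + self.h2_polygenic <= 1:
            raise ValueError("h2_qtl + h2_polygenic must lie in [0,1]")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < min <= max <= 0.5")
        chroms = {self.chrom_name(i) for i in range(self.n_chromosomes)}
        for c in self.causal_snps:
            if c.chrom not in chroms:
                raise ValueError(f"causal SNP chromosome {c.chrom} not simulated")
            if not 1 <= c.pos <= self.chromosome_length:
                raise ValueError(f"causal position {c.pos} off chromosome")

    def chrom_name(self, i: int) -> str:
        return f"Chr{i + 1}"


def _subpop_labels(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    counts = np.floor(np.asarray(config.subpop_fractions) * config.n_accessions)
    counts = counts.astype(int)
    # distribute the rounding remainder to the largest fractions
    rem = config.n_accessions - counts.sum()
    order = np.argsort(config.subpop_fractions)[::-1]
    for k in range(rem):
        counts[order[k % len(counts)]] += 1
    labels = np.repeat(np.asarray(config.subpop_labels), counts)
    return labels


def simulate_genotypes(config: SimConfig, return_frequencies: bool = False):
    """Generate an inbred-panel dosage matrix plus subpopulation labels.

    Dosages are 0/2 (fully homozygous) apart from a configurable residual
    heterozygosity; causal SNP positions from the config are injected as
    actual simulated sites. With ``return_frequencies`` the drawn
    per-subpopulation alt-allele frequencies (n_subpops x n_snps) are
    returned as a third element, for calibration checks.
    """
    rng = np.random.default_rng(config.seed)
    labels = _subpop_labels(config, rng)
    # row of each accession in the per-subpopulation frequency table
    lab_to_k = {lab: k for k, lab in enumerate(config.subpop_labels)}
    acc_sub = np.array([lab_to_k[l] for l in labels])

    n = config.n_accessions
    n_sub = len(config.subpop_labels)
    F = config.fst
    lo, hi = config.maf_range

    chroms, positions, dosage_blocks, freq_blocks = [], [], [], []
    for ci in range(config.n_chromosomes):
        cname = config.chrom_name(ci)
        forced = sorted({c.pos for c in config.causal_snps if c.chrom == cname})
        m_free = config.snps_per_chromosome - len(forced)
        if m_free < 0:
            raise ValueError("more causal SNPs than SNPs on a chromosome")
        want = min(m_free * 2 + 10, config.chromosome_length)
        pos = rng.choice(config.chromosome_length, size=want, replace=False) + 1
        pos = np.setdiff1d(pos, np.asarray(forced, dtype=np.int64))
        if pos.size < m_free:
            raise ValueError("chromosome too short for requested SNP count")
        pos = rng.permutation(pos)[:m_free]
        pos = np.sort(np.concatenate([pos, np.asarray(forced, dtype=np.int64)]))
        m = pos.size

        # allele frequencies are drawn per LD block and shared (with small
        # per-SNP jitter) by the block's SNPs: SNPs on one haplotype block
        # necessarily have similar frequencies, and without this sharing the
        # pooled two-subpopulation dosage r^2 would not reach realistic
        # within-block levels
        block = pos // config.ld_block_length
        block_ids, block_of = np.unique(block, return_inverse=True)
        nb = block_ids.size
        maf_b = rng.uniform(lo, hi, size=nb)
        flip = rng.random(nb) < 0.5
        p_anc_b = np.where(flip, 1.0 - maf_b, maf_b)
        a = p_anc_b * (1.0 - F) / F
        b = (1.0 - p_anc_b) * (1.0 - F) / F
        p_sub_b = rng.beta(a, b, size=(n_sub, nb))
        # blocks holding a planted causal SNP must stay common in every
        # subpopulation so the configured effect is actually expressed
        forced_blocks = np.unique(
            np.asarray(forced, dtype=np.int64) // config.ld_block_length)
        for jb in np.flatnonzero(np.isin(block_ids, forced_blocks)):
            for _ in range(1000):
                pj = rng.uniform(0.35, 0.65)
                draw = rng.beta(pj * (1.0 - F) / F, (1.0 - pj) * (1.0 - F) / F,
                                size=n_sub)
                if np.all((draw >= 0.2) & (draw <= 0.8)):
                    p_sub_b[:, jb] = draw
                    break
            else:
                p_sub_b[:, jb] = np.clip(p_sub_b[:, jb], 0.2, 0.8)
        jitter = rng.normal(0.0, 0.02, size=m)
        p_sub = np.clip(p_sub_b[:, block_of] + jitter, 0.02, 0.98)

        # haplotype-copying chain: each accession carries a latent uniform
        # per SNP that is copied from the previous SNP with probability
        # exp(-d / ld_block_length) (a shared haplotype lineage) or drawn
        # fresh, so dosage r^2 decays roughly as exp(-2d/L) with distance
        rho = np.exp(-np.diff(pos) / config.ld_block_length)
        u = np.empty((n, m))
        u[:, 0] = rng.random(n)
        for j in range(1, m):
            fresh = rng.random(n)
            copy = rng.random(n) < rho[j - 1]
            u[:, j] = np.where(copy, u[:, j - 1], fresh)
        allele = (u < p_sub[acc_sub, :]).astype(float)
        dos = 2.0 * allele
        if config.residual_het > 0:
            het = rng.random((n, m)) < config.residual_het
            dos[het] = 1.0
        if config.missing_rate > 0:
            miss = rng.random((n, m)) < config.missing_rate
            dos[miss] = np.nan
        chroms.append(np.full(m, cname, dtype=object))
        positions.append(pos)
        dosage_blocks.append(dos)
        freq_blocks.append(p_sub)

    m_total = sum(p.size for p in positions)
    G = GenotypeMatrix(
        accessions=[f"ACC{i:04d}" for i in range(n)],
        chrom=np.concatenate(chroms),
        pos=np.concatenate(positions),
        ref=np.full(m_total, "A", dtype=object),
        alt=np.full(m_total, "T", dtype=object),
        dosages=np.concatenate(dosage_blocks, axis=1),
    )
    if return_frequencies:
        return G, labels, np.concatenate(freq_blocks, axis=1)
    return G, labels


def simulate_phenotype(G: GenotypeMatrix, config: SimConfig,
                       labels: np.ndarray) -> tuple[pd.DataFrame, dict]:
    """TFC-like phenotypes with planted QTL, polygenic and noise components.

    value = baseline + sum(effect * dosage) + polygenic (cov ~ kinship,
    scaled to h2_polygenic of total variance) + independent noise; two field
    replicates per accession differ by replicate-level noise. Returns the
    phenotype table and a truth sidecar (causal SNPs, realized variance
    fractions).
    """
    rng = np.random.default_rng(config.seed + 1)
    n = G.n_accessions
    labels = np.asarray(labels)

    g = np.zeros(n)
    X = G.imputed()
    for c in config.causal_snps:
        try:
            j = G.snp_index(c.chrom, c.pos)
        except KeyError as exc:
            raise KeyError(
                f"causal SNP {c.chrom}:{c.pos} absent from genotype matrix"
            ) from exc
        dose = X[:, j].copy()
        if c.scope != "both":
            dose = np.where(labels == c.scope, dose, 0.0)
        g += c.effect * dose

    var_g = float(np.var(g))
    if config.h2_qtl > 0 and var_g > 0:
        total_var = var_g / config.h2_qtl
    else:
        total_var = config.base_sd**2
    h2_poly = config.h2_polygenic
    u = np.zeros(n)
    if h2_poly > 0:
        K = kinship(G)
        # jitter keeps the Cholesky stable for a near-singular realized K
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        u = L @ rng.standard_normal(n)
        sd_u = u.std()
        if sd_u > 0:
            u *= np.sqrt(h2_poly * total_var) / sd_u
    h2_used = (config.h2_qtl if var_g > 0 else 0.0) + h2_poly
    var_e = max(total_var * (1.0 - h2_used), 0.0)
    e = rng.standard_normal(n) * np.sqrt(var_e)

    y = config.baseline_tfc + g + u + e
    rep1 = y + rng.standard_normal(n) * config.replicate_sd
    rep2 = y + rng.standard_normal(n) * config.replicate_sd
    mean_tfc = (rep1 + rep2) / 2.0

    status = np.where(rng.random(n) < 0.7, "landrace", "improved")
    lat = rng.uniform(18.0, 45.0, n).round(2)
    lon = rng.uniform(95.0, 125.0, n).round(2)
    table = pd.DataFrame({
        "accession": G.accessions,
        "rep1": rep1,
        "rep2": rep2,
        "mean_tfc": mean_tfc,
        "subpop": labels,
        "origin": [f"{a},{o}" for a, o in zip(lat, lon)],
        "improvement_status": status,
    })
    vt = float(np.var(mean_tfc))
    truth = {
        "causal_snps": [asdict(c) for c in config.causal_snps],
        "h2_qtl_requested": config.h2_qtl,
        "h2_polygenic_requested": config.h2_polygenic,
        "var_qtl_realized": var_g / vt if vt > 0 else 0.0,
        "var_polygenic_realized": float(np.var(u)) / vt if vt > 0 else 0.0,
        "total_variance": vt,
        "seed": config.seed,
    }
    return table, truth


def simulate_annotation(config: SimConfig, gene_density: float = 30.0,
                        transposon_fraction: float = 0.15,
                        hypothetical_fraction: float = 0.10,
                        seed: int | None = None) -> list[GeneModel]:
    """Non-overlapping toy gene models across the simulated chromosomes.

    ``gene_density`` is genes per Mb; counts are Poisson per chromosome.
    ``transposon_fraction`` of models are labelled transposon or
    retrotransposon (split evenly), ``hypothetical_fraction`` hypothetical,
    the rest "gene". Gene bodies are 2-6 kb with 1-5 exons and UTR stubs.
    """
    if gene_density <= 0:
        raise ValueError("gene_density must be positive")
    if transposon_fraction + hypothetical_fraction > 1:
        raise ValueError("class fractions exceed 1")
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    genes: list[GeneModel] = []
    counter = 1
    for ci in range(config.n_chromosomes):
        cname = config.chrom_name(ci)
        L = config.chromosome_length
        n_genes = int(rng.poisson(gene_density * L / 1e6))
        if n_genes == 0:
            continue
        lengths = rng.integers(2000, 6001, size=n_genes)
        total = int(lengths.sum())
        slack = L - total - n_genes  # >=1 bp between consecutive genes
        if slack < 0:
            raise ValueError(
                f"gene density {gene_density}/Mb too high to place "
                f"{n_genes} genes on a {L} bp chromosome without overlap")
        gaps = rng.dirichlet(np.ones(n_genes + 1)) * slack
        gaps = np.floor(gaps).astype(int)
        pos = 1
        for gi in range(n_genes):
            pos += int(gaps[gi]) + 1
            start, end = pos, pos + int(lengths[gi]) - 1
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 6))
            if n_ex == 1:
                exons = [(start, end)]
            else:
                cuts = np.sort(rng.choice(
                    np.arange(start + 100, end - 100), size=2 * (n_ex - 1),
                    replace=False))
                bounds = [start, *cuts.tolist(), end]
                exons = [(int(bounds[2 * k]), int(bounds[2 * k + 1]))
                         for k in range(n_ex)]
            u = rng.random()
            if u < transposon_fraction / 2:
                g_class = "transposon"
            elif u < transposon_fraction:
                g_class = "retrotransposon"
            elif u < transposon_fraction + hypothetical_fraction:
                g_class = "hypothetical"
            else:
                g_class = "gene"
            first, last = exons[0], exons[-1]
            stub5 = (first[0], min(first[0] + 99, first[1]))
            stub3 = (max(last[1] - 99, last[0]), last[1])
            if strand == "-":
                stub5, stub3 = stub3, stub5
            genes.append(GeneModel(
                gene_id=f"SIMG{counter:05d}", chrom=cname, strand=strand,
                start=start, end=end, gene_class=g_class, exons=exons,
                utr5=[stub5], utr3=[stub3]))
            counter += 1
    return genes


def simulate_expression(genes: list[GeneModel],
                        tissues: tuple[str, ...] = GRAIN_TISSUES,
                        expressed_fraction: float = 0.6,
                        seed: int = 0,
                        timepoints: tuple[int, ...] = (7, 14, 21),
                        high_genes: tuple[str, ...] = (),
                        high_level: float = 25.0) -> pd.DataFrame:
    """Per gene x tissue x timepoint expression levels (linear units).

    ``1 - expressed_fraction`` of genes get level 0 in every grain tissue;
    genes listed in ``high_genes`` are forced above ``high_level`` in at
    least one grain tissue.
    """
    if not genes:
        raise ValueError("empty gene set")
    if not tissues:
        raise ValueError("empty tissue list")
    rng = np.random.default_rng(seed)
    ids = [g.gene_id for g in genes]
    expressed = rng.random(len(ids)) < expressed_fraction
    rows = []
    for gi, gid in enumerate(ids):
        force_high = gid in high_genes
        on = expressed[gi] or force_high
        for t in tissues:
            for tp in timepoints:
                if not on:
                    level = 0.0
                else:
                    level = float(rng.lognormal(mean=1.5, sigma=1.0))
                rows.append((gid, t, tp, level))
    expr = pd.DataFrame(rows, columns=["gene_id", "tissue", "timepoint", "level"])
    for gid in high_genes:
        sub = expr["gene_id"] == gid
        if not (expr.loc[sub, "level"] > high_level).any():
            first = expr.index[sub][0]
            expr.loc[first, "level"] = high_level * (1.5 + rng.random())
    return expr


def simulate_absorbance(tfc_values, curve: StandardCurve,
                        dilution: DilutionScheme | None = None,
                        noise_sd: float = 0.0,
                        seed: int = 0) -> np.ndarray:
    """Raw assay absorbances that invert to the given TFC values.

    absorbance = slope * (tfc / multiplier) + intercept + N(0, noise_sd);
    at zero noise absorbance_to_tfc recovers the input exactly. TFC values
    implying a reaction concentration outside the standard-curve range are
    flagged with a warning but still produced.
    """
    if dilution is None:
        dilution = DilutionScheme()
    rng = np.random.default_rng(seed)
    v = np.asarray(tfc_values, dtype=float)
    conc = v / dilution.multiplier
    lo, hi = curve.concentration_range
    out_of_range = (conc < lo) | (conc > hi)
    if np.any(out_of_range):
        warnings.warn(
            f"{int(out_of_range.sum())} TFC value(s) imply concentrations "
            f"outside the standard range [{lo},{hi}] mg/mL", stacklevel=2)
    a = curve.slope * conc + curve.intercept
    if noise_sd > 0:
        a = a + rng.standard_normal(a.shape) * noise_sd
    return a
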