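"""Core in-memory containers shared across the pipeline.

The genotype container holds an accessions x SNPs dosage matrix (alt-allele
counts 0/1/2, ``nan`` for missing) with 1-based SNP coordinates, the layout
produced by parsing a biallelic VCF of an inbred diversity panel. Gene models
carry the feature intervals (exons, derived introns, UTR stubs) and the class
label (gene / transposon / retrotransposon / hypothetical) that the
candidate-gene funnel filters on.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = np.nan


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs dosage matrix with 1-based SNP coordinates.

    Parameters
    ----------
    accessions
        Accession identifiers, one per matrix row.
    chrom
        Chromosome name per SNP (column).
    pos
        1-based physical position per SNP; strictly increasing within each
        chromosome.
    ref, alt
        Reference / alternate allele per SNP.
    dosages
        ``(n_accessions, n_snps)`` float array of alt-allele counts in
        {0, 1, 2}; missing calls are ``nan``.
    """

    accessions: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.accessions), len(self.pos)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.pos)} SNPs"
            )
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"dosages outside {{0,1,2,missing}}: {bad}")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def snp_ids(self) -> list[str]:
        return [f"{c}_{p}" for c, p in zip(self.chrom, self.pos)]

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP over non-missing calls."""
        with np.errstate(invalid="ignore"):
            p_alt = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p_alt, 1.0 - p_alt)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the SNP columns in ``index`` (kept order)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            accessions=list(self.accessions),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosages=self.dosages[:, index],
        )

    def take_accessions(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            accessions=[self.accessions[i] for i in index],
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            dosages=self.dosages[index, :],
        )

    def snp_index(self, chrom: str, pos: int) -> int:
        """Column index of the SNP at (chrom, pos); raises if absent."""
        hits = np.flatnonzero((self.chrom == str(chrom)) & (self.pos == int(pos)))
        if hits.size == 0:
            raise KeyError(f"SNP {chrom}:{pos} not present in matrix")
        return int(hits[0])

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-SNP mean."""
        X = self.dosages.copy()
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(X))
        X[idx] = col_mean[idx[1]]
        return X


@dataclass
class GeneModel:
    """A gene with feature intervals, all 1-based inclusive as in GFF3."""

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    start: int
    end: int
    gene_class: str = "gene"  # gene | transposon | retrotransposon | hypothetical
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.start > self.end:
            raise ValueError(f"start > end for {self.gene_id}")
        for s, e in self.exons + self.utr5 + self.utr3:
            if s < self.start or e > self.end:
                raise ValueError(f"feature [{s},{e}] outside span of {self.gene_id}")
        self.exons = sorted(self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def promoter(self, promoter_len: int = 2000) -> tuple[int, int]:
        """Upstream window of length ``promoter_len`` respecting strand.

        On the + strand the window is [start - promoter_len, start - 1]; on
        the - strand it mirrors to [end + 1, end + promoter_len].
        """
        if self.strand == "+":
            return (max(1, self.start - promoter_len), self.start - 1)
        return (self.end + 1, self.end + promoter_len)
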