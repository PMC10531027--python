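"""SNP quality control, LD pruning, kinship, PCA and pairwise r^2.

These are the inputs the mixed model and the LD-based interval analyses
require: SNPs are filtered on biallelism, missing rate and MAF; a pruned,
roughly independent SNP set feeds PCA; the full QC'd set feeds a VanRaden
centered kinship matrix. Boundary semantics follow the filtering rules the
pipeline is built around: missing rate strictly over the threshold and MAF
strictly under the threshold are removed, so missing <= 0.30 and
MAF >= 0.05 are retained.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix


@dataclass
class QCReport:
    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_retained: int
    max_missing: float
    min_maf: float
    n_removed_multiallelic: int = 0

    def __post_init__(self) -> None:
        total = (self.n_retained + self.n_removed_missing
                 + self.n_removed_maf + self.n_removed_multiallelic)
        if total != self.n_input:
            raise ValueError("QC counts do not sum to n_input")


@dataclass
class PcaResult:
    coordinates: np.ndarray  # (n_accessions, n_components)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def filter_snps(G: GenotypeMatrix, max_missing: float = 0.30,
                min_maf: float = 0.05,
                n_removed_multiallelic: int = 0) -> tuple[GenotypeMatrix, QCReport]:
    """Retain SNPs with missing rate <= max_missing and MAF >= min_maf.

    MAF is computed on non-missing dosages. Multiallelic sites are dropped
    at VCF parse time; their count is threaded through for the report.
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0,1]")
    if G.n_snps == 0:
        raise ValueError("empty genotype matrix")
    miss = G.missing_rate()
    maf = G.maf()
    fail_missing = miss > max_missing
    # all-missing columns have undefined MAF; they fail the missing filter
    fail_maf = ~fail_missing & (np.isnan(maf) | (maf < min_maf))
    keep = ~fail_missing & ~fail_maf
    report = QCReport(
        n_input=G.n_snps + n_removed_multiallelic,
        n_removed_multiallelic=n_removed_multiallelic,
        n_removed_missing=int(fail_missing.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_retained=int(keep.sum()),
        max_missing=max_missing,
        min_maf=min_maf,
    )
    return G.take_snps(np.flatnonzero(keep)), report


def pairwise_r2(G: GenotypeMatrix, snp_i: int, snp_j: int) -> float:
    """Squared Pearson correlation of dosages at two SNP columns.

    Computed over accessions non-missing at both SNPs; returns nan (with a
    warning) when fewer than two complete observations remain or either SNP
    has zero variance among them.
    """
    a = G.dosages[:, snp_i]
    b = G.dosages[:, snp_j]
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        warnings.warn(f"r^2 undefined for SNP pair ({snp_i},{snp_j})",
                      stacklevel=2)
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Pairwise dosage r^2 for a small set of SNP columns (pairwise-complete)."""
    m = dosages.shape[1]
    out = np.full((m, m), np.nan)
    for i in range(m):
        out[i, i] = 1.0
        for j in range(i + 1, m):
            a, b = dosages[:, i], dosages[:, j]
            ok = ~np.isnan(a) & ~np.isnan(b)
            aa, bb = a[ok], b[ok]
            if aa.size < 2 or aa.std() == 0 or bb.std() == 0:
                continue
            r = np.corrcoef(aa, bb)[0, 1]
            out[i, j] = out[j, i] = r * r
    return out


def ld_prune(G: GenotypeMatrix, window_snps: int = 50, step_snps: int = 5,
             r2_max: float = 0.3, window_unit: str = "snps") -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained SNP column indices.

    Within each window, while any retained pair exceeds ``r2_max``, the
    member of the worst (highest-r^2) pair with the higher missing rate is
    dropped (tie -> the higher column index). Windows advance by
    ``step_snps`` within each chromosome. ``window_unit`` may be "snps"
    (PLINK-style SNP-count windows, the default) or "bp".
    """
    if window_unit not in ("snps", "bp"):
        raise ValueError("window_unit must be 'snps' or 'bp'")
    if not window_snps >= step_snps >= 1:
        raise ValueError("need window >= step >= 1")
    miss = G.missing_rate()
    removed = np.zeros(G.n_snps, dtype=bool)
    for c in np.unique(G.chrom):
        cols = np.flatnonzero(G.chrom == c)
        start = 0
        while start < cols.size:
            if window_unit == "snps":
                win = cols[start:start + window_snps]
            else:
                left_pos = G.pos[cols[start]]
                in_win = G.pos[cols[start:]] < left_pos + window_snps
                win = cols[start:][in_win]
            live = win[~removed[win]]
            if live.size > 1:
                r2 = _r2_matrix(G.dosages[:, live])
                np.fill_diagonal(r2, np.nan)
                while True:
                    keep_mask = ~removed[live]
                    idx = np.flatnonzero(keep_mask)
                    if idx.size < 2:
                        break
                    sub = r2[np.ix_(idx, idx)]
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        worst = np.nanmax(sub)
                    if not (worst > r2_max):
                        break
                    i, j = np.unravel_index(np.nanargmax(sub), sub.shape)
                    gi, gj = live[idx[i]], live[idx[j]]
                    if miss[gi] > miss[gj]:
                        removed[gi] = True
                    elif miss[gj] > miss[gi]:
                        removed[gj] = True
                    else:
                        removed[max(gi, gj)] = True
            start += step_snps
    return np.flatnonzero(~removed)


def kinship(G: GenotypeMatrix, method: str = "vanraden") -> np.ndarray:
    """Accession x accession relatedness matrix.

    ``vanraden`` (default): centered-dosage cross-product scaled by
    2*sum(p*(1-p)) over SNPs, with per-SNP mean imputation of missing
    dosages before centering. ``ibs``: proportion of shared alleles.
    """
    if G.n_accessions < 2:
        raise ValueError("kinship needs at least 2 accessions")
    if np.any(np.all(np.isnan(G.dosages), axis=0)):
        raise ValueError("all-missing SNP column; run QC first")
    if method == "vanraden":
        X = G.imputed()
        p = X.mean(axis=0) / 2.0
        Z = X - 2.0 * p
        denom = 2.0 * np.sum(p * (1.0 - p))
        if denom == 0:
            raise ValueError("no polymorphic SNPs for kinship")
        return (Z @ Z.T) / denom
    if method == "ibs":
        X = G.imputed()
        n = G.n_accessions
        K = np.empty((n, n))
        for i in range(n):
            K[i, :] = 1.0 - np.abs(X[i] - X).mean(axis=1) / 2.0
        return (K + K.T) / 2.0
    raise ValueError(f"unknown kinship method {method!r}")


def pca(G: GenotypeMatrix, n_components: int = 3) -> PcaResult:
    """PCA of the centered, mean-imputed dosage matrix.

    Components are ordered by eigenvalue; each component's sign is fixed so
    its largest-magnitude accession loading is positive.
    """
    n = G.n_accessions
    if n_components >= n:
        raise ValueError("n_components must be < n_accessions")
    X = G.imputed()
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    if not np.any(s > 0):
        # zero-variance panel (e.g. identical accessions): every accession
        # sits at the origin of every component
        return PcaResult(coordinates=np.zeros((n, n_components)),
                         explained_variance_ratio=np.zeros(n_components))
    rank = int(np.sum(s > s[0] * 1e-12))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    coords = U[:, :n_components] * s[:n_components]
    for k in range(n_components):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    var = s**2
    evr = var[:n_components] / var.sum() if var.sum() > 0 else var[:n_components]
    return PcaResult(coordinates=coords, explained_variance_ratio=evr)
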