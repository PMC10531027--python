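"""Mixed-linear-model association scan and permutation thresholds.

The single-trait model is

    y = [1, Q] beta + g gamma + u + e,   u ~ N(0, sigma_g^2 K),
                                         e ~ N(0, sigma_e^2 I)

with Q the leading principal components and K the (optionally compressed)
kinship matrix. Variance components are estimated once under the null by
REML on the spectrally decomposed model (EMMA-style 1-D profile over
delta = sigma_e^2 / sigma_g^2) and reused for every SNP test (P3D). Each
SNP's mean-imputed dosage then enters as a fixed effect; effect and SE come
from generalized least squares in the whitened (rotated) space and the
p-value from a t distribution with n - q - 1 degrees of freedom, q being
the number of null-model covariates including the intercept. Because the
residual scale is re-estimated per SNP, the scan collapses exactly onto
per-SNP OLS when K is the identity and there are no covariates.

Genome-wide significance is calibrated by permutation: the phenotype is
permuted, delta is re-estimated with the cached eigendecomposition, the
whole genome re-scanned, and the maximum -log10(p) recorded; the threshold
is an empirical quantile (type-7) of those maxima.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import GenotypeMatrix

_DELTA_GRID = np.logspace(-5, 5, 100)


@dataclass
class NullModelFit:
    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float
    eigenvalues: np.ndarray
    rotation: np.ndarray  # eigenvectors of K, columns


@dataclass
class CompressionPlan:
    n_groups: int
    assignment: np.ndarray  # accession index -> group id (0-based)
    group_kinship: np.ndarray  # (n_groups, n_groups) averaged kinship

    def expanded(self) -> np.ndarray:
        """Accession-level covariance implied by the grouped kinship."""
        return self.group_kinship[np.ix_(self.assignment, self.assignment)]


def _check_psd(K: np.ndarray) -> None:
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix is not symmetric")
    w = np.linalg.eigvalsh(K)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ValueError("kinship matrix is not positive semi-definite")


def _design(n: int, Q: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if Q is not None and np.size(Q):
        Q = np.asarray(Q, dtype=float)
        if Q.ndim == 1:
            Q = Q[:, None]
        if Q.shape[0] != n:
            raise ValueError("covariate rows do not match phenotype length")
        X = np.hstack([X, Q])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular covariate matrix")
    return X


def _reml_loglik(delta: float, ys: np.ndarray, Xs: np.ndarray,
                 lam: np.ndarray) -> float:
    """Restricted log-likelihood profiled over sigma_g^2 at fixed delta."""
    n, q = Xs.shape
    D = lam + delta
    w = 1.0 / D
    XtWX = Xs.T @ (Xs * w[:, None])
    XtWy = Xs.T @ (ys * w)
    beta = np.linalg.solve(XtWX, XtWy)
    r = ys - Xs @ beta
    rss = float(r @ (r * w))
    df = n - q
    sigma_g2 = rss / df
    _, logdet_XtWX = np.linalg.slogdet(XtWX)
    _, logdet_XtX = np.linalg.slogdet(Xs.T @ Xs)
    return float(-0.5 * (df * np.log(2.0 * np.pi * sigma_g2) + df
                         + np.sum(np.log(D)) + logdet_XtWX - logdet_XtX))


def _optimize_delta(ys: np.ndarray, Xs: np.ndarray,
                    lam: np.ndarray) -> tuple[float, float]:
    """Grid search over delta refined by bounded scalar optimization."""
    lls = np.array([_reml_loglik(d, ys, Xs, lam) for d in _DELTA_GRID])
    k = int(np.argmax(lls))
    lo = _DELTA_GRID[max(k - 1, 0)]
    hi = _DELTA_GRID[min(k + 1, _DELTA_GRID.size - 1)]
    res = optimize.minimize_scalar(
        lambda d: -_reml_loglik(d, ys, Xs, lam),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6 * max(1.0, lo)})
    delta = float(res.x)
    return delta, _reml_loglik(delta, ys, Xs, lam)


def fit_null(y: np.ndarray, Q: np.ndarray | None, K: np.ndarray | None,
             eig: tuple[np.ndarray, np.ndarray] | None = None) -> NullModelFit:
    """REML variance components for the null (no-SNP) mixed model.

    ``eig`` allows reuse of a cached eigendecomposition of K (values,
    vectors); K itself is then ignored. The profile over delta is evaluated
    on a 100-point log grid in [1e-5, 1e5] and refined by bounded scalar
    optimization to ~1e-6 relative.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if np.var(y) == 0:
        raise ValueError("zero phenotypic variance")
    X = _design(n, Q)
    if eig is None:
        _check_psd(K)
        lam, U = np.linalg.eigh(K)
        lam = np.maximum(lam, 0.0)
    else:
        lam, U = eig
    ys = U.T @ y
    Xs = U.T @ X
    delta, ll = _optimize_delta(ys, Xs, lam)
    D = lam + delta
    w = 1.0 / D
    beta = np.linalg.solve(Xs.T @ (Xs * w[:, None]), Xs.T @ (ys * w))
    r = ys - Xs @ beta
    sigma_g2 = float(r @ (r * w)) / (n - X.shape[1])
    return NullModelFit(
        sigma_g2=sigma_g2, sigma_e2=sigma_g2 * delta, delta=delta,
        reml_loglik=ll, eigenvalues=lam, rotation=U)


def compress_kinship(K: np.ndarray, n_groups: int,
                     method: str = "average") -> CompressionPlan:
    """Cluster accessions and average kinship within group pairs.

    Hierarchical clustering on distance 1 - K/max(diag K) with the given
    linkage; grouped kinship entry (g, h) is the mean of all member-pair
    kinships (including diagonal entries for g == h).
    """
    n = K.shape[0]
    if not 1 <= n_groups <= n:
        raise ValueError(f"n_groups must lie in [1, {n}]")
    if n_groups == n:
        return CompressionPlan(n_groups=n, assignment=np.arange(n),
                               group_kinship=K.copy())
    scale = float(np.max(np.diag(K)))
    D = 1.0 - K / (scale if scale > 0 else 1.0)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=method)
    assignment = fcluster(Z, t=n_groups, criterion="maxclust") - 1
    n_found = int(assignment.max()) + 1
    M = np.zeros((n_found, n))
    for g in range(n_found):
        members = assignment == g
        M[g, members] = 1.0 / members.sum()
    return CompressionPlan(n_groups=n_found, assignment=assignment,
                           group_kinship=M @ K @ M.T)


def select_compression(y: np.ndarray, Q: np.ndarray | None, K: np.ndarray,
                       candidate_group_counts: list[int]
                       ) -> tuple[CompressionPlan, NullModelFit]:
    """Pick the group count whose null-model REML likelihood is largest.

    Ties prefer fewer groups (candidates are tried in increasing order and
    a later candidate must strictly beat the incumbent).
    """
    if not candidate_group_counts:
        raise ValueError("empty candidate list")
    best = None
    for g in sorted(set(int(c) for c in candidate_group_counts)):
        plan = compress_kinship(K, g)
        fit = fit_null(y, Q, plan.expanded())
        if best is None or fit.reml_loglik > best[1].reml_loglik + 1e-9:
            best = (plan, fit)
    return best


def default_group_counts(n: int) -> list[int]:
    """Candidate compression levels: {1, n/8, n/4, n/2, n}, rounded."""
    cands = {1, round(n / 8), round(n / 4), round(n / 2), n}
    return sorted(c for c in cands if 1 <= c <= n)


class RotatedScan:
    """Cached rotated design for repeated whole-genome scans.

    Rotating the genotype matrix into the kinship eigenbasis is the
    expensive step; caching it makes the permutation loop O(n*m) per
    permutation instead of O(n^2*m).
    """

    def __init__(self, G: GenotypeMatrix, Q: np.ndarray | None,
                 lam: np.ndarray, U: np.ndarray):
        n = G.n_accessions
        self.n = n
        self.lam = lam
        self.U = U
        self.X0 = _design(n, Q)
        self.q = self.X0.shape[1]
        self.X0s = U.T @ self.X0
        self.Gs = U.T @ G.imputed()
        self.maf = G.maf()

    def scan(self, ys: np.ndarray, delta: float
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """GLS effect, SE and p per SNP at fixed delta; ys is rotated y."""
        w = 1.0 / np.sqrt(self.lam + delta)
        yw = ys * w
        X0w = self.X0s * w[:, None]
        Gw = self.Gs * w[:, None]
        Qx, _ = np.linalg.qr(X0w)
        y_t = yw - Qx @ (Qx.T @ yw)
        G_t = Gw - Qx @ (Qx.T @ Gw)
        gg = np.einsum("ij,ij->j", G_t, G_t)
        gy = G_t.T @ y_t
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = gy / gg
            df = self.n - self.q - 1
            rss = np.maximum(float(y_t @ y_t) - beta * gy, 0.0)
            se = np.sqrt(rss / df / gg)
            tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        return beta, se, p


def associate(G: GenotypeMatrix, y: np.ndarray, Q: np.ndarray | None,
              K_or_plan, p3d: bool = True, min_maf: float = 0.0,
              population: str = "full",
              null_fit: NullModelFit | None = None) -> pd.DataFrame:
    """Single-marker mixed-model scan; returns one row per SNP.

    Columns: chrom, pos, effect, se, p, neg_log10_p, maf, population,
    skipped. SNPs below ``min_maf`` (or monomorphic / all-missing) are
    flagged skipped with missing statistics. With ``p3d=False`` delta is
    re-estimated per SNP with the SNP in the fixed effects (slow; small
    panels only).
    """
    y = np.asarray(y, dtype=float)
    K = K_or_plan.expanded() if isinstance(K_or_plan, CompressionPlan) else K_or_plan
    if null_fit is None:
        null_fit = fit_null(y, Q, K)
    lam, U = null_fit.eigenvalues, null_fit.rotation
    rs = RotatedScan(G, Q, lam, U)
    ys = U.T @ y
    skipped = np.isnan(rs.maf) | (rs.maf < min_maf) | (rs.maf == 0)

    if p3d:
        beta, se, p = rs.scan(ys, null_fit.delta)
    else:
        m = G.n_snps
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        p = np.full(m, np.nan)
        X = G.imputed()
        base_Q = None if Q is None else np.asarray(Q, dtype=float)
        for j in range(m):
            if skipped[j]:
                continue
            gj = X[:, j][:, None]
            Qj = gj if base_Q is None else np.hstack(
                [base_Q if base_Q.ndim == 2 else base_Q[:, None], gj])
            fit_j = fit_null(y, Qj, K, eig=(lam, U))
            Xs_full = U.T @ _design(rs.n, Qj)
            bj, sj, pj = _single_gls(ys, U.T @ rs.X0, Xs_full[:, -1],
                                     lam, fit_j.delta, rs.n, rs.q)
            beta[j], se[j], p[j] = bj, sj, pj

    beta = np.where(skipped, np.nan, beta)
    se = np.where(skipped, np.nan, se)
    p = np.where(skipped, np.nan, p)
    p = np.where(np.isnan(p), p, np.clip(p, np.finfo(float).tiny, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        nlp = -np.log10(p)
    return pd.DataFrame({
        "chrom": G.chrom,
        "pos": G.pos,
        "effect": beta,
        "se": se,
        "p": p,
        "neg_log10_p": nlp,
        "maf": rs.maf,
        "population": population,
        "skipped": skipped,
    })


def _single_gls(ys, X0s, gs, lam, delta, n, q):
    w = 1.0 / np.sqrt(lam + delta)
    yw = ys * w
    X0w = X0s * w[:, None]
    gw = gs * w
    Qx, _ = np.linalg.qr(X0w)
    y_t = yw - Qx @ (Qx.T @ yw)
    g_t = gw - Qx @ (Qx.T @ gw)
    gg = float(g_t @ g_t)
    if gg == 0:
        return np.nan, np.nan, np.nan
    beta = float(g_t @ y_t) / gg
    df = n - q - 1
    rss = max(float(y_t @ y_t) - beta * float(g_t @ y_t), 0.0)
    se = np.sqrt(rss / df / gg)
    if se == 0:
        return beta, se, 0.0
    t = beta / se
    return beta, se, 2.0 * stats.t.sf(abs(t), df)


@dataclass
class ThresholdResult:
    maxima: np.ndarray  # per-permutation max -log10(p)
    quantile: float
    threshold: float
    n_perm: int
    seed: int


def permutation_threshold(G: GenotypeMatrix, y: np.ndarray,
                          Q: np.ndarray | None, K: np.ndarray,
                          n_perm: int = 1000, quantile: float = 0.95,
                          seed: int = 0, min_maf: float = 0.0,
                          refit_delta: bool = True) -> ThresholdResult:
    """Genome-wide significance threshold from permutation maxima.

    Each permutation shuffles y (breaking genotype links while keeping the
    phenotype distribution), re-estimates delta with the cached kinship
    eigendecomposition, scans all SNPs, and records the maximum -log10(p);
    the threshold is the ``quantile`` of the maxima under type-7 (linear)
    interpolation.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20: quantile unstable")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    base = fit_null(y, Q, K)
    lam, U = base.eigenvalues, base.rotation
    rs = RotatedScan(G, Q, lam, U)
    skipped = np.isnan(rs.maf) | (rs.maf < min_maf) | (rs.maf == 0)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        ys = U.T @ yp
        if refit_delta:
            delta, _ = _optimize_delta(ys, rs.X0s, lam)
        else:
            delta = base.delta
        _, _, p = rs.scan(ys, delta)
        p = np.where(skipped, np.nan, p)
        pmin = np.nanmin(np.clip(p, np.finfo(float).tiny, 1.0))
        maxima[b] = -np.log10(pmin)
    threshold = float(np.quantile(maxima, quantile))  # numpy default = type 7
    return ThresholdResult(maxima=maxima, quantile=quantile,
                           threshold=threshold, n_perm=n_perm, seed=seed)
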