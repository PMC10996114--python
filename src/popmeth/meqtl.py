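"""Mixed-linear-model meQTL mapping.

Each DMR's per-accession methylation level is a trait: rank-based
inverse-normal transformed, then scanned against SNP dosages under the
model y = X b + u + e with u ~ N(0, sigma_g^2 K) for an identity-by-state
kinship K.  The variance-component ratio delta = sigma_e^2 / sigma_g^2 is
fitted once per trait by REML on the eigendecomposition of K and held
fixed across SNPs (the EMMAX approximation), turning every SNP test into
a weighted least-squares Wald t-test in the rotated basis.  Significant
associations are Bonferroni-thresholded, LD-clumped (r^2 < 0.25) and
classified local/distal by the 1-Mb rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtri

from .popgen_scan import GenotypeMatrix


def inverse_normal_transform(values: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    x_i -> Phi^{-1}((rank_i - c) / (n - 2c + 1)) over the non-missing
    entries (average ranks for ties); missing values stay missing.  If
    every value is identical all outputs are 0 (with a warning).
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    n = ok.sum()
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    v = x[ok]
    if np.ptp(v) == 0:
        warnings.warn("all values identical; transform is all zeros")
        out[ok] = 0.0
        return out
    ranks = stats.rankdata(v, method="average")
    out[ok] = ndtri((ranks - c) / (n - 2 * c + 1))
    return out


def ibs_kinship(dosage: np.ndarray) -> np.ndarray:
    """Identity-by-state kinship: K_ij = mean_snp(1 - |d_i - d_j| / 2).

    ``dosage`` is (n_snps, n_samples) with NaN missing; missing entries
    are pairwise-deleted.  Diagonal is exactly 1.
    """
    d = np.asarray(dosage, dtype=float)
    n = d.shape[1]
    if np.isnan(d).all(axis=0).any():
        raise ValueError("an accession has all-missing genotypes")
    K = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(d[:, i]) | np.isnan(d[:, j]))
            if not ok.any():
                raise ValueError(f"no shared genotyped SNPs for pair ({i}, {j})")
            K[i, j] = K[j, i] = float(
                np.mean(1.0 - np.abs(d[ok, i] - d[ok, j]) / 2.0)
            )
    return K


@dataclass
class LmmNull:
    """Per-trait null mixed-model fit, reused across the SNP scan."""

    delta: float  # sigma_e^2 / sigma_g^2
    sigma_g2: float
    sigma_e2: float
    eigenvalues: np.ndarray
    rotation: np.ndarray  # U such that K = U diag(eigenvalues) U^T
    loglik: float
    heritability: float  # sigma_g^2 / (sigma_g^2 + sigma_e^2)


def _reml_loglik(log_delta, lam, yr, Xr, logdet_xx):
    """Restricted log-likelihood profiled over the variance scale."""
    delta = np.exp(log_delta)
    w = lam + delta
    n, p = Xr.shape
    Wi = 1.0 / w
    XtWX = Xr.T @ (Xr * Wi[:, None])
    XtWy = Xr.T @ (yr * Wi)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yr - Xr @ beta
    rss = float(resid @ (resid * Wi))
    nf = n - p
    sigma_g2 = rss / nf
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    ll = -0.5 * (
        nf * (np.log(2 * np.pi * sigma_g2) + 1)
        + np.sum(np.log(w))
        + logdet_xwx
        - logdet_xx
    )
    return ll, sigma_g2, beta


def lmm_null_fit(
    y: np.ndarray,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    log_delta_bounds: tuple[float, float] = (-10.0, 10.0),
) -> LmmNull:
    """REML fit of the null model y = X b + u + e, u ~ N(0, sigma_g^2 K).

    The kinship is eigendecomposed once; delta is optimised by a coarse
    grid over log delta followed by Brent refinement.  Near-zero or
    negative eigenvalues (numerical) are floored at 1e-6 with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if np.isnan(y).any():
        raise ValueError("drop missing trait values before fitting")
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    lam, U = np.linalg.eigh((K + K.T) / 2)
    if lam.min() < 1e-6:
        if lam.min() < -1e-8:
            warnings.warn("kinship not PSD; flooring eigenvalues at 1e-6")
        lam = np.maximum(lam, 1e-6)
    yr = U.T @ y
    Xr = U.T @ X
    _, logdet_xx = np.linalg.slogdet(X.T @ X)

    grid = np.linspace(*log_delta_bounds, 41)
    lls = [_reml_loglik(g, lam, yr, Xr, logdet_xx)[0] for g in grid]
    k = int(np.argmax(lls))
    lo = grid[max(0, k - 1)]
    hi = grid[min(len(grid) - 1, k + 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, lam, yr, Xr, logdet_xx)[0],
        bounds=(lo, hi),
        method="bounded",
    )
    best = res.x if -res.fun >= max(lls) else grid[k]
    ll, sigma_g2, _ = _reml_loglik(best, lam, yr, Xr, logdet_xx)
    delta = float(np.exp(best))
    sigma_e2 = sigma_g2 * delta
    return LmmNull(
        delta=delta,
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        eigenvalues=lam,
        rotation=U,
        loglik=float(ll),
        heritability=float(sigma_g2 / (sigma_g2 + sigma_e2)),
    )


@dataclass(frozen=True)
class MeqtlAssociation:
    snp_id: str
    snp_chrom: str
    snp_pos: int  # 1-based
    dmr_id: str
    beta: float
    se: float
    p_value: float
    distance: float = np.inf
    locality: str = ""


def lmm_scan(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    null: LmmNull,
    dmr_id: str,
    covariates: np.ndarray | None = None,
) -> list[MeqtlAssociation]:
    """EMMAX-style scan of one transformed trait across all SNPs.

    With delta fixed from the null fit, each SNP's Wald t-test is a
    weighted least-squares regression in the rotated basis; the residual
    variance is re-estimated per SNP, so with K = I the test reduces
    exactly to ordinary simple regression.  Missing dosages are
    mean-imputed per SNP; SNPs monomorphic in the analysed samples are
    skipped.  Two-sided p from t with n - rank(X) - 1 df.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != len(genotypes.samples):
        raise ValueError("trait / genotype sample mismatch")
    X0 = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    U, lam = null.rotation, null.eigenvalues
    w = lam + null.delta
    Wi = 1.0 / w
    yr = U.T @ y
    X0r = U.T @ X0

    G = genotypes.dosage.T.copy()  # samples x snps
    col_mean = np.nanmean(G, axis=0)
    nan_mask = np.isnan(G)
    G[nan_mask] = np.broadcast_to(col_mean, G.shape)[nan_mask]
    poly = np.nanstd(G, axis=0) > 0
    Gr = U.T @ G

    A = X0r.T @ (X0r * Wi[:, None])
    Ainv = np.linalg.inv(A)
    coef_y = Ainv @ (X0r.T @ (yr * Wi))
    ry = yr - X0r @ coef_y
    coef_g = Ainv @ (X0r.T @ (Gr * Wi[:, None]))
    Rg = Gr - X0r @ coef_g

    gwg = np.einsum("ij,ij->j", Rg, Rg * Wi[:, None])
    gwy = np.einsum("ij,i->j", Rg, ry * Wi)
    yy = float(ry @ (ry * Wi))
    df = n - X0.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough samples for the Wald test")
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = gwy / gwg
        rss = yy - beta * gwy
        se = np.sqrt(np.maximum(rss, 0) / df / gwg)
        tstat = beta / se
    pvals = 2 * stats.t.sf(np.abs(tstat), df)
    out = []
    snps = genotypes.snps
    ids = snps["id"].to_numpy()
    chroms = snps["chrom"].to_numpy()
    poss = snps["pos"].to_numpy()
    for k in np.flatnonzero(poly & np.isfinite(tstat)):
        out.append(
            MeqtlAssociation(
                snp_id=str(ids[k]),
                snp_chrom=str(chroms[k]),
                snp_pos=int(poss[k]),
                dmr_id=dmr_id,
                beta=float(beta[k]),
                se=float(se[k]),
                p_value=float(pvals[k]),
            )
        )
    return out


def bonferroni_threshold(n_tests: int, alpha: float = 0.01) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class ClumpedSet:
    retained: list[str]
    r2_threshold: float


def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (pairwise complete)."""
    ok = ~(np.isnan(g1) | np.isnan(g2))
    a, b = g1[ok], g2[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_clump(
    associations: list[MeqtlAssociation],
    genotypes: GenotypeMatrix,
    r2_max: float = 0.25,
    window: int = 1_000_000,
) -> ClumpedSet:
    """Greedy p-value-ranked LD clumping.

    Repeatedly accept the most significant remaining SNP and discard
    SNPs within ``window`` bp on the same chromosome whose genotype r^2
    with any accepted SNP is >= ``r2_max``.
    """
    snp_col = {s: i for i, s in enumerate(genotypes.snps["id"])}
    pending = sorted(associations, key=lambda a: (a.p_value, a.snp_id))
    accepted: list[MeqtlAssociation] = []
    removed: set[str] = set()
    for cand in pending:
        if cand.snp_id in removed:
            continue
        ok = True
        for acc in accepted:
            if (
                acc.snp_chrom == cand.snp_chrom
                and abs(acc.snp_pos - cand.snp_pos) <= window
                and genotype_r2(
                    genotypes.dosage[snp_col[acc.snp_id]],
                    genotypes.dosage[snp_col[cand.snp_id]],
                )
                >= r2_max
            ):
                ok = False
                break
        if ok:
            accepted.append(cand)
        else:
            removed.add(cand.snp_id)
    return ClumpedSet(retained=[a.snp_id for a in accepted], r2_threshold=r2_max)


def classify_local_distal(
    associations: list[MeqtlAssociation],
    dmr_coords: dict[str, tuple[str, int, int]],
    local_dist: int = 1_000_000,
) -> list[MeqtlAssociation]:
    """Label each association local (within 1 Mb of its DMR) or distal.

    Distance is from the SNP position to the nearest DMR edge (0 when the
    SNP lies inside); SNPs on a different chromosome are distal.
    """
    out = []
    for a in associations:
        chrom, start, end = dmr_coords[a.dmr_id]
        pos0 = a.snp_pos - 1
        if a.snp_chrom != chrom:
            dist, loc = np.inf, "distal"
        else:
            if start <= pos0 < end:
                dist = 0
            else:
                dist = start - pos0 if pos0 < start else pos0 - (end - 1)
            loc = "local" if dist <= local_dist else "distal"
        out.append(
            MeqtlAssociation(
                snp_id=a.snp_id,
                snp_chrom=a.snp_chrom,
                snp_pos=a.snp_pos,
                dmr_id=a.dmr_id,
                beta=a.beta,
                se=a.se,
                p_value=a.p_value,
                distance=float(dist),
                locality=loc,
            )
        )
    return out


def pure_dmr_fraction(
    dmr_ids: list[str], significant: list[MeqtlAssociation]
) -> tuple[float, list[str]]:
    """Fraction of DMRs with no significant association ('pure DMRs')."""
    tagged = {a.dmr_id for a in significant}
    pure = [d for d in dmr_ids if d not in tagged]
    return (len(pure) / len(dmr_ids) if dmr_ids else np.nan), pure


def genomic_control_lambda(pvalues: np.ndarray) -> float:
    """Genomic-inflation factor: median chi2(1) quantile ratio."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
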