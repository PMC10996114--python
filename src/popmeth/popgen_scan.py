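"""Sliding-window population genetics: pi, F_ST, and sweep regions.

Nucleotide diversity uses the unbiased per-site estimator
pi = 2 j (n - j) / (n (n - 1)) for alt-allele count j among n called
alleles, summed over SNPs in 10-kb windows advanced in 1-kb steps and
divided by the window span (the VCFtools --window-pi convention).
Differentiation uses the Weir & Cockerham (1984) variance-component
estimator, windowed as a ratio of sums; negative estimates are kept.
Windows in the top decile of both the ancestral/derived pi ratio and
F_ST define selective-sweep regions (DSRs), merged when overlapping or
book-ended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (0/1/2, NaN missing), samples in columns."""

    snps: pd.DataFrame  # columns chrom, pos (1-based), ref, alt, id
    dosage: np.ndarray  # (n_snps, n_samples) float
    samples: list[str]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def sample_index(self, names) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise ValueError(f"samples not in genotype matrix: {missing}")
        return np.array([pos[n] for n in names], dtype=int)


@dataclass(frozen=True)
class SweepRegion:
    chrom: str
    start: int
    end: int
    comparison: str
    n_windows: int


def read_vcf_genotypes(
    path,
    samples: list[str] | None = None,
    maf_min: float = 0.05,
    max_missing: float = 0.7,
) -> GenotypeMatrix:
    """Load biallelic SNP dosages from a VCF, applying MAF/missingness filters.

    Keeps sites with minor-allele frequency >= ``maf_min`` (computed on
    non-missing calls) and per-site missing rate <= ``max_missing``;
    multiallelic records are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if samples is not None:
        absent = [s for s in samples if s not in vcf_samples]
        if absent:
            raise ValueError(f"samples missing from VCF {path}: {absent}")
        order = [vcf_samples.index(s) for s in samples]
    else:
        samples = vcf_samples
        order = list(range(len(vcf_samples)))
    rows, dosages = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        gt = np.array(v.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        d = np.where(gt == 3, 2.0, gt)
        d[gt == 2] = np.nan
        d = d[order]
        miss = np.isnan(d).mean()
        if miss > max_missing:
            continue
        called = d[~np.isnan(d)]
        if len(called) == 0:
            continue
        af = called.sum() / (2 * len(called))
        if min(af, 1 - af) < maf_min:
            continue
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], v.ID or f"{v.CHROM}:{v.POS}"))
        dosages.append(d)
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "id"])
    dosage = (
        np.array(dosages) if dosages else np.empty((0, len(samples)))
    )
    return GenotypeMatrix(snps=snps, dosage=dosage, samples=list(samples))


def site_pi(alt_count: float, called_alleles: int) -> float:
    """Per-site nucleotide diversity 2 j (n - j) / (n (n - 1))."""
    j, n = alt_count, called_alleles
    if n < 2:
        return float("nan")
    if not 0 <= j <= n:
        raise ValueError("require 0 <= alt_count <= called_alleles")
    return 2.0 * j * (n - j) / (n * (n - 1))


def _per_site_pi(gm: GenotypeMatrix, cols: np.ndarray) -> np.ndarray:
    d = gm.dosage[:, cols]
    called = ~np.isnan(d)
    n = 2 * called.sum(axis=1)
    j = np.nansum(d, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    pi[n < 2] = np.nan
    return pi


def _windows(length: int, window: int, step: int):
    start = 0
    while start < length:
        yield start, min(start + window, length)
        start += step


def window_diversity(
    gm: GenotypeMatrix,
    samples: list[str],
    chrom_lengths: dict[str, int],
    window: int = 10_000,
    step: int = 1_000,
) -> pd.DataFrame:
    """Per-bp pi in sliding windows (sum of site pi / window span)."""
    if window < step:
        raise ValueError("window must be >= step")
    cols = gm.sample_index(samples)
    pi = _per_site_pi(gm, cols)
    pos0 = gm.snps["pos"].to_numpy() - 1
    out = []
    for chrom, length in chrom_lengths.items():
        on = (gm.snps["chrom"] == chrom).to_numpy()
        p = pos0[on]
        v = np.nan_to_num(pi[on])
        order = np.argsort(p, kind="stable")
        p, v = p[order], v[order]
        csum = np.concatenate([[0.0], np.cumsum(v)])
        for start, end in _windows(length, window, step):
            lo, hi = np.searchsorted(p, [start, end])
            out.append((chrom, start, end, (csum[hi] - csum[lo]) / (end - start)))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "pi"])


def wc_fst_components(
    d_a: np.ndarray, d_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components (a, b, c) for two pops.

    ``d_a``/``d_b`` are (n_snps, n_samples) diploid dosage arrays with
    NaN missing.  Sites with fewer than two called diploids in either
    population get NaN components and are excluded from window sums.
    """
    r = 2.0
    comps = []
    ns, ps, hs = [], [], []
    for d in (d_a, d_b):
        called = ~np.isnan(d)
        n_i = called.sum(axis=1).astype(float)  # diploids
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.nansum(d, axis=1) / (2 * n_i)
            h_i = np.nansum(d == 1, axis=1) / n_i  # observed het frequency
        ns.append(n_i)
        ps.append(p_i)
        hs.append(h_i)
    n1, n2 = ns
    p1, p2 = ps
    h1, h2 = hs
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2
    for arr in (a, b, c):
        arr[~valid] = np.nan
    return a, b, c


def window_fst(
    gm: GenotypeMatrix,
    samples_a: list[str],
    samples_b: list[str],
    chrom_lengths: dict[str, int],
    window: int = 10_000,
    step: int = 1_000,
) -> pd.DataFrame:
    """Windowed Weir-Cockerham theta = sum(a) / sum(a + b + c).

    Ratio-of-sums across the window's SNPs; negative estimates are kept;
    windows with zero total variance are NaN.
    """
    d_a = gm.dosage[:, gm.sample_index(samples_a)]
    d_b = gm.dosage[:, gm.sample_index(samples_b)]
    a, b, c = wc_fst_components(d_a, d_b)
    num = np.nan_to_num(a)
    den = np.nan_to_num(a + b + c)
    pos0 = gm.snps["pos"].to_numpy() - 1
    out = []
    for chrom, length in chrom_lengths.items():
        on = (gm.snps["chrom"] == chrom).to_numpy()
        p = pos0[on]
        order = np.argsort(p, kind="stable")
        p = p[order]
        cnum = np.concatenate([[0.0], np.cumsum(num[on][order])])
        cden = np.concatenate([[0.0], np.cumsum(den[on][order])])
        for start, end in _windows(length, window, step):
            lo, hi = np.searchsorted(p, [start, end])
            dsum = cden[hi] - cden[lo]
            theta = (cnum[hi] - cnum[lo]) / dsum if dsum > 0 else np.nan
            out.append((chrom, start, end, theta))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "fst"])


def merge_intervals(
    intervals: list[tuple[str, int, int]]
) -> list[tuple[str, int, int, int]]:
    """Merge overlapping or book-ended (gap 0) intervals per chromosome.

    Returns (chrom, start, end, n_merged) with maximal merged regions.
    """
    out = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e, n = ivs[0][0], ivs[0][1], 1
        for s, e in ivs[1:]:
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
                n += 1
            else:
                out.append((chrom, cur_s, cur_e, n))
                cur_s, cur_e, n = s, e, 1
        out.append((chrom, cur_s, cur_e, n))
    return out


def sweep_scan(
    windows: pd.DataFrame,
    comparison: str = "",
    top_fraction: float = 0.10,
) -> tuple[dict, list[SweepRegion]]:
    """Joint top-decile pi-ratio / F_ST sweep scan.

    ``windows`` must carry columns chrom, start, end, pi_ancestral,
    pi_derived, fst.  The pi ratio is ancestral/derived; windows whose
    derived pi is 0 (or whose statistics are missing) are excluded from
    the ratio ranking and logged.  Empirical (1 - top_fraction) quantiles
    of the remaining ratios and of F_ST are the thresholds; windows
    strictly exceeding BOTH are merged into sweep regions.  The
    thresholds are data properties and are returned alongside.
    """
    need = {"chrom", "start", "end", "pi_ancestral", "pi_derived", "fst"}
    if not need.issubset(windows.columns):
        raise ValueError(f"windows frame must have columns {sorted(need)}")
    if len(windows) < 10:
        raise ValueError("fewer than 10 windows: top-decile quantile ill-defined")
    w = windows.copy()
    zero_den = (w["pi_derived"] <= 0) | w["pi_derived"].isna()
    if zero_den.any():
        logger.info(
            "excluding %d windows with zero/missing derived pi from ratio ranking",
            int(zero_den.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        w["pi_ratio"] = np.where(
            ~zero_den, w["pi_ancestral"] / w["pi_derived"], np.nan
        )
    ratio_thr = float(np.nanquantile(w["pi_ratio"], 1 - top_fraction))
    fst_thr = float(np.nanquantile(w["fst"], 1 - top_fraction))
    sel = (w["pi_ratio"] > ratio_thr) & (w["fst"] > fst_thr)
    merged = merge_intervals(
        [
            (r.chrom, int(r.start), int(r.end))
            for r in w[sel.fillna(False)].itertuples(index=False)
        ]
    )
    regions = [
        SweepRegion(chrom=c, start=s, end=e, comparison=comparison, n_windows=n)
        for c, s, e, n in merged
    ]
    thresholds = {
        "pi_ratio": ratio_thr,
        "fst": fst_thr,
        "n_selected_windows": int(sel.fillna(False).sum()),
        "n_excluded_zero_pi": int(zero_den.sum()),
    }
    return thresholds, regions


def region_diversity(
    gm: GenotypeMatrix,
    regions: list[tuple[str, int, int]],
    samples: list[str],
) -> pd.DataFrame:
    """Per-bp pi of arbitrary half-open regions for one population."""
    cols = gm.sample_index(samples)
    pi = np.nan_to_num(_per_site_pi(gm, cols))
    pos0 = gm.snps["pos"].to_numpy() - 1
    chroms = gm.snps["chrom"].to_numpy()
    out = []
    for chrom, start, end in regions:
        if end <= start:
            raise ValueError(f"zero-length region {chrom}:{start}-{end}")
        sel = (chroms == chrom) & (pos0 >= start) & (pos0 < end)
        out.append((chrom, start, end, pi[sel].sum() / (end - start)))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "pi"])
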