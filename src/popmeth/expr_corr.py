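"""Methylation-expression relationships.

Expression-quartile metaprofiles (genes binned into low / mid-low /
mid-high / high expression groups) and per-gene Pearson correlation
between a DMR's methylation level and the nearby gene's expression
across accessions.  Expression is log2(FPKM + 1)-transformed before
correlating; Pearson r is invariant to affine rescaling of the raw
values, so FPKM-like units are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .methylome_core import MethylationMatrix, Metaprofile, feature_metaprofile

EXPRESSION_GROUPS = ("low", "mid-low", "mid-high", "high")


def read_expression(path) -> pd.DataFrame:
    """Genes x accessions FPKM-like matrix from TSV (first column gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    return df


def expression_quartile_groups(
    expression: pd.DataFrame, accessions: list[str] | None = None
) -> pd.Series:
    """Assign genes to four expression groups by mean level.

    Genes are sorted ascending by mean expression over the requested
    accessions (ties broken by input gene order, which keeps the
    assignment stable) and split into four contiguous chunks of
    near-equal size, earlier chunks taking the extra gene when the count
    is not divisible by 4.  All-zero genes sort first and land in 'low'.
    """
    if len(expression) < 4:
        raise ValueError("need at least 4 genes")
    sub = expression if accessions is None else expression[accessions]
    means = sub.mean(axis=1)
    order = np.argsort(means.to_numpy(), kind="stable")
    n = len(order)
    sizes = [(n + 3 - i) // 4 for i in range(4)]  # earlier chunks get extras
    labels = np.empty(n, dtype=object)
    start = 0
    for g, size in zip(EXPRESSION_GROUPS, sizes):
        labels[order[start : start + size]] = g
        start += size
    return pd.Series(labels, index=expression.index, name="group")


def groupwise_metaprofile(
    matrix: MethylationMatrix,
    genes: pd.DataFrame,
    groups: pd.Series,
    context: str,
    flank: int = 2_000,
    accessions=None,
) -> dict[str, Metaprofile]:
    """One 20/40/20-bin metaprofile per expression group."""
    out = {}
    for g in EXPRESSION_GROUPS:
        members = groups.index[groups == g]
        feats = genes[genes["gene_id"].isin(members)]
        if feats.empty:
            import warnings

            warnings.warn(f"expression group {g!r} has no genes; profile missing")
            out[g] = None
            continue
        out[g] = feature_metaprofile(
            matrix, feats, context=context, flank=flank, accessions=accessions, label=g
        )
    return out


@dataclass(frozen=True)
class DmrGeneCorrelation:
    dmr_id: str
    gene_id: str
    location: str  # upstream / body / downstream
    pcc: float
    p_value: float
    n: int


def dmr_expression_correlation(
    dmr_levels: pd.DataFrame,
    expression: pd.DataFrame,
    pairs: pd.DataFrame,
    log_transform: bool = True,
    min_pairs: int = 5,
) -> list[DmrGeneCorrelation]:
    """Pearson correlation of DMR methylation vs gene expression.

    ``dmr_levels`` is DMR x accession methylation levels, ``pairs`` has
    columns region_id (a DMR id), gene_id and location.  Expression is
    log2(FPKM + 1)-transformed by default.  Pairs with fewer than
    ``min_pairs`` jointly non-missing accessions, or with a constant
    vector, are reported with NaN correlation.
    """
    shared = [a for a in dmr_levels.columns if a in expression.columns]
    expr = expression[shared]
    if log_transform:
        expr = np.log2(expr + 1.0)
    out = []
    for row in pairs.itertuples(index=False):
        if row.region_id not in dmr_levels.index or row.gene_id not in expr.index:
            continue
        m = dmr_levels.loc[row.region_id, shared].to_numpy(dtype=float)
        e = expr.loc[row.gene_id].to_numpy(dtype=float)
        ok = ~(np.isnan(m) | np.isnan(e))
        r, p, n = np.nan, np.nan, int(ok.sum())
        if n >= min_pairs and np.ptp(m[ok]) > 0 and np.ptp(e[ok]) > 0:
            r, p = stats.pearsonr(m[ok], e[ok])
        out.append(
            DmrGeneCorrelation(
                dmr_id=str(row.region_id),
                gene_id=str(row.gene_id),
                location=row.location,
                pcc=float(r),
                p_value=float(p),
                n=n,
            )
        )
    return out


def correlation_summary(
    correlations: list[DmrGeneCorrelation], strong: float = 0.5
) -> dict:
    """Distribution summary: counts and the fraction with |r| > ``strong``."""
    r = np.array([c.pcc for c in correlations if not np.isnan(c.pcc)])
    return {
        "n_pairs": len(correlations),
        "n_with_r": len(r),
        "fraction_strong": float(np.mean(np.abs(r) > strong)) if len(r) else np.nan,
        "mean_r": float(r.mean()) if len(r) else np.nan,
        "median_r": float(np.median(r)) if len(r) else np.nan,
    }
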