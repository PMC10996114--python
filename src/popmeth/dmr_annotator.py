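"""Interval algebra over DMRs, sweep regions and genome annotation.

Covers CG/CHG overlap grouping (the co-evolution analysis), genomic
composition with an explicit label precedence, gene-proximity pairing,
region sharing between processes, and methylation PCA.  All intervals
are 0-based half-open; touching intervals never overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .dmr_caller import Dmr
from .methylome_core import MethylationMatrix


@dataclass
class AnnotationSet:
    """Genes (with exons), TEs and chromosome lengths.

    Derived categories: introns = gene body minus exons; flanks = 2 kb on
    each side of a gene body; intergenic = the complement.
    """

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    exons: pd.DataFrame  # gene_id, chrom, start, end
    tes: pd.DataFrame  # chrom, start, end, te_class
    chrom_lengths: dict[str, int]

    def __post_init__(self):
        bodies = self.genes.set_index("gene_id")
        for ex in self.exons.itertuples(index=False):
            g = bodies.loc[ex.gene_id]
            if not (g.start <= ex.start < ex.end <= g.end):
                raise ValueError(
                    f"exon {ex.start}-{ex.end} outside gene body of {ex.gene_id}"
                )


def read_gff3_genes(path, chrom_lengths: dict[str, int] | None = None):
    """Read gene and exon intervals from a GFF3 file (0-based half-open out).

    Exons may name either the gene or an mRNA of the gene as Parent.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes, exons = [], []
    for g in db.features_of_type("gene"):
        genes.append((g.id, g.seqid, g.start - 1, g.end, g.strand))
    for ex in db.features_of_type("exon"):
        parents = list(db.parents(ex, featuretype="gene"))
        if not parents:
            parents = [p for p in db.parents(ex)]
        gene_id = parents[0].id if parents else ex.attributes.get("Parent", ["?"])[0]
        exons.append((gene_id, ex.seqid, ex.start - 1, ex.end))
    genes_df = pd.DataFrame(
        genes, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    exons_df = pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"])
    return genes_df, exons_df


def read_bed_tes(path) -> pd.DataFrame:
    """Read TE intervals from a BED file (name column = TE class)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "te_class"]
    return df


@dataclass
class OverlapGroups:
    """Partition of CG/CHG DMRs by cross-context overlap (>= 1 bp)."""

    o_pairs: list[tuple[Dmr, Dmr]]
    o_cg: list[Dmr]
    o_chg: list[Dmr]
    u_cg: list[Dmr]
    u_chg: list[Dmr]


def classify_context_overlap(
    cg_dmrs: list[Dmr], chg_dmrs: list[Dmr]
) -> OverlapGroups:
    """Assign DMRs to overlapping (o_CG_CHG) and unique (u_CG / u_CHG) groups.

    Half-open convention: book-ended regions do not overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for k, d in enumerate(chg_dmrs):
        trees.setdefault(d.chrom, IntervalTree()).addi(d.start, d.end, k)
    o_pairs, o_cg_idx, o_chg_idx = [], set(), set()
    for i, d in enumerate(cg_dmrs):
        tree = trees.get(d.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(d.start, d.end), key=lambda h: h.begin):
            o_pairs.append((d, chg_dmrs[hit.data]))
            o_cg_idx.add(i)
            o_chg_idx.add(hit.data)
    return OverlapGroups(
        o_pairs=o_pairs,
        o_cg=[d for i, d in enumerate(cg_dmrs) if i in o_cg_idx],
        o_chg=[d for i, d in enumerate(chg_dmrs) if i in o_chg_idx],
        u_cg=[d for i, d in enumerate(cg_dmrs) if i not in o_cg_idx],
        u_chg=[d for i, d in enumerate(chg_dmrs) if i not in o_chg_idx],
    )


def _pooled_region_level(
    matrix: MethylationMatrix, chrom, start, end, context, cols
) -> float:
    mask = matrix.site_mask(chrom, start, end) & (
        matrix.sites["context"] == context
    ).to_numpy()
    supported = matrix.total[mask][:, cols] > matrix.min_reads
    m = np.where(supported, matrix.meth[mask][:, cols], 0).sum()
    t = np.where(supported, matrix.total[mask][:, cols], 0).sum()
    return m / t if t > 0 else np.nan


def coevolution_correlation(
    groups: OverlapGroups,
    matrix: MethylationMatrix,
    populations: dict[str, list[str]],
) -> dict:
    """CG vs CHG methylation correlation across DMRs of each overlap group.

    For o_CG_CHG pairs the union region is used; for unique groups the
    DMR's own region is scored in both contexts (cross-context level at
    the matched locus).  One point per (DMR, population), with counts
    pooled over the population's accessions; Pearson r per population and
    over all points ('pooled').  Groups with < 3 usable DMRs report NaN.
    """
    regions = {
        "o_cg_chg": [
            (a.chrom, min(a.start, b.start), max(a.end, b.end))
            for a, b in groups.o_pairs
        ],
        "u_cg": [(d.chrom, d.start, d.end) for d in groups.u_cg],
        "u_chg": [(d.chrom, d.start, d.end) for d in groups.u_chg],
    }
    out = {}
    for name, regs in regions.items():
        pts: dict[str, list[tuple[float, float]]] = {p: [] for p in populations}
        for chrom, start, end in regs:
            for pop, members in populations.items():
                cols = matrix.accession_index(members)
                x = _pooled_region_level(matrix, chrom, start, end, "CG", cols)
                y = _pooled_region_level(matrix, chrom, start, end, "CHG", cols)
                if not (np.isnan(x) or np.isnan(y)):
                    pts[pop].append((x, y))
        res = {}
        all_pts = [p for v in pts.values() for p in v]
        for label, p in [("pooled", all_pts)] + list(pts.items()):
            arr = np.array(p) if p else np.empty((0, 2))
            if len(arr) < 3 or arr[:, 0].std() == 0 or arr[:, 1].std() == 0:
                res[label] = {"r": np.nan, "p": np.nan, "n": len(arr)}
                continue
            r, pval = stats.pearsonr(arr[:, 0], arr[:, 1])
            slope, intercept = np.polyfit(arr[:, 0], arr[:, 1], 1)
            res[label] = {
                "r": float(r),
                "p": float(pval),
                "n": len(arr),
                "slope": float(slope),
                "intercept": float(intercept),
            }
        out[name] = res
    return out


COMPOSITION_LABELS = ["intergenic", "flank", "te", "intron", "exon"]


def _label_arrays(
    ann: AnnotationSet, flank: int = 2_000, te_over_intron: bool = False
) -> dict[str, np.ndarray]:
    """Per-bp label codes with precedence exon > intron > TE > flank by
    default (TE > intron when ``te_over_intron``); intergenic elsewhere."""
    code = {lab: i for i, lab in enumerate(COMPOSITION_LABELS)}
    arrays = {
        c: np.zeros(length, dtype=np.uint8) for c, length in ann.chrom_lengths.items()
    }

    def paint(df, label):
        for r in df.itertuples(index=False):
            arr = arrays[r.chrom]
            arr[max(0, r.start) : min(len(arr), r.end)] = code[label]

    flanks = []
    for g in ann.genes.itertuples(index=False):
        flanks.append((g.chrom, g.start - flank, g.start))
        flanks.append((g.chrom, g.end, g.end + flank))
    flank_df = pd.DataFrame(flanks, columns=["chrom", "start", "end"])
    paint(flank_df, "flank")
    if te_over_intron:
        paint(ann.genes[["chrom", "start", "end"]], "intron")
        paint(ann.tes[["chrom", "start", "end"]], "te")
    else:
        paint(ann.tes[["chrom", "start", "end"]], "te")
        paint(ann.genes[["chrom", "start", "end"]], "intron")
    paint(ann.exons[["chrom", "start", "end"]], "exon")
    return arrays


def genomic_composition(
    regions: list[tuple[str, int, int]],
    ann: AnnotationSet,
    flank: int = 2_000,
    te_over_intron: bool = False,
    merge_flank_into_intergenic: bool = False,
) -> dict[str, float]:
    """bp fractions of a region set over exon/intron/TE/flank/intergenic.

    Every bp gets exactly one label by precedence, so fractions sum to 1.
    ``merge_flank_into_intergenic`` gives the merged view in which gene
    flanks are reported as intergenic.
    """
    arrays = _label_arrays(ann, flank, te_over_intron)
    counts = np.zeros(len(COMPOSITION_LABELS), dtype=np.int64)
    for chrom, start, end in regions:
        if chrom not in arrays:
            raise ValueError(f"region on unknown chromosome {chrom!r}")
        arr = arrays[chrom]
        if start < 0 or end > len(arr) or end <= start:
            raise ValueError(f"region {chrom}:{start}-{end} outside chromosome")
        counts += np.bincount(arr[start:end], minlength=len(COMPOSITION_LABELS))
    total = counts.sum()
    frac = {lab: counts[i] / total for i, lab in enumerate(COMPOSITION_LABELS)}
    if merge_flank_into_intergenic:
        frac["intergenic"] += frac.pop("flank")
    return frac


def genes_near_regions(
    regions: list[tuple[str, int, int]],
    genes: pd.DataFrame,
    flank: int = 2_000,
    region_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Pair regions with genes they touch, labelled upstream/body/downstream.

    A gene is near a region when the region overlaps the gene body or
    either 2-kb flank; labels are strand-aware (upstream = 5' flank) and
    body takes priority when a region spans a boundary.
    """
    if region_ids is None:
        region_ids = [f"region_{i:05d}" for i in range(len(regions))]
    trees: dict[str, IntervalTree] = {}
    for i, (chrom, start, end) in enumerate(regions):
        trees.setdefault(chrom, IntervalTree()).addi(start, end, i)
    rows = []
    for g in genes.itertuples(index=False):
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        if g.strand == "-":
            up = (g.end, g.end + flank)
            down = (g.start - flank, g.start)
        else:
            up = (g.start - flank, g.start)
            down = (g.end, g.end + flank)
        for label, (s, e) in [("body", (g.start, g.end)), ("upstream", up), ("downstream", down)]:
            if e <= s:
                continue
            for hit in tree.overlap(s, e):
                rows.append((region_ids[hit.data], g.gene_id, label))
    df = pd.DataFrame(rows, columns=["region_id", "gene_id", "location"])
    # body outranks flank labels for the same (region, gene)
    order = {"body": 0, "upstream": 1, "downstream": 2}
    df["_rank"] = df["location"].map(order)
    df = (
        df.sort_values(["region_id", "gene_id", "_rank"])
        .drop_duplicates(["region_id", "gene_id"])
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return df


def _merge_bp(intervals):
    from .popgen_scan import merge_intervals

    return [(c, s, e) for c, s, e, _ in merge_intervals(list(intervals))]


def shared_regions(
    set_a: list[tuple[str, int, int]], set_b: list[tuple[str, int, int]]
) -> dict:
    """Region-count overlap (>= 1 bp) and bp-level Jaccard of two sets."""
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in set_b:
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    n_a_overlap = sum(
        1
        for chrom, s, e in set_a
        if chrom in trees and trees[chrom].overlaps(s, e)
    )
    trees_a: dict[str, IntervalTree] = {}
    for chrom, s, e in set_a:
        trees_a.setdefault(chrom, IntervalTree()).addi(s, e)
    n_b_overlap = sum(
        1
        for chrom, s, e in set_b
        if chrom in trees_a and trees_a[chrom].overlaps(s, e)
    )
    ma = _merge_bp(set_a) if set_a else []
    mb = _merge_bp(set_b) if set_b else []

    def total_bp(ivs):
        return sum(e - s for _, s, e in ivs)

    inter = 0
    tb: dict[str, IntervalTree] = {}
    for chrom, s, e in mb:
        tb.setdefault(chrom, IntervalTree()).addi(s, e)
    for chrom, s, e in ma:
        for hit in tb.get(chrom, IntervalTree()).overlap(s, e):
            inter += min(e, hit.end) - max(s, hit.begin)
    union = total_bp(ma) + total_bp(mb) - inter
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_a_overlapping": n_a_overlap,
        "n_b_overlapping": n_b_overlap,
        "jaccard_bp": inter / union if union else np.nan,
    }


def methylation_pca(
    matrix: MethylationMatrix, context: str, n_components: int = 2
):
    """Centered (unscaled) PCA of accessions on site methylation levels.

    Missing cells are mean-imputed per site (complete-case deletion can
    empty the matrix at realistic missingness).  Returns (coordinates
    DataFrame accessions x PCs, explained-variance fractions).
    """
    from sklearn.decomposition import PCA

    sub = matrix.subset_context(context)
    if len(sub.accessions) < 3:
        raise ValueError("PCA needs at least 3 accessions")
    lv = sub.levels.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        site_mean = np.nanmean(lv, axis=1)
    keep = ~np.isnan(site_mean)
    lv, site_mean = lv[keep], site_mean[keep]
    nan_cells = np.isnan(lv)
    lv[nan_cells] = np.broadcast_to(site_mean[:, None], lv.shape)[nan_cells]
    X = lv.T  # accessions x sites
    X = X - X.mean(axis=0)
    k = min(n_components, len(sub.accessions) - 1, X.shape[1])
    if np.allclose(X, 0):
        coords = np.zeros((len(sub.accessions), k))
        evr = np.zeros(k)
    else:
        pca = PCA(n_components=k, svd_solver="full")
        coords = pca.fit_transform(X)
        evr = pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=sub.accessions, columns=cols), evr
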