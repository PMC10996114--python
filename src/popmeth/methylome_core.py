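"""Per-accession methylome handling.

Parses Bismark-style cytosine reports, pools biological replicates by
summing read counts, applies the read-support filter, and assembles a
sites x accessions methylation-level matrix that downstream DMR calling,
PCA, metaprofiles and correlation analyses all consume.

Coordinate conventions: cytosine reports carry 1-based positions (file
convention); every interval handled internally is 0-based half-open, and
a site at 1-based position ``pos`` occupies 0-based coordinate ``pos-1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONTEXTS = ("CG", "CHG", "CHH")

REPORT_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "n_meth",
    "n_unmeth",
    "context",
    "trinucleotide",
]


@dataclass(frozen=True)
class CytosineSiteRecord:
    """A single cytosine's observation in one sample."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if not (0 <= self.n_meth <= self.n_total):
            raise ValueError("require 0 <= n_meth <= n_total")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def level(self) -> float:
        return self.n_meth / self.n_total if self.n_total else float("nan")


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a 7-column cytosine report into a records frame.

    Columns: chrom, 1-based pos, strand, methylated count, unmethylated
    count, context, trinucleotide.  Returns a frame with ``n_total``
    (= methylated + unmethylated); rows keep file order.  Sites with zero
    coverage are kept here and removed later by :func:`filter_coverage`.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=REPORT_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "trinucleotide": str,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed cytosine report {path}: {exc}") from exc
    if df.empty:
        return _empty_records()
    for col in ("pos", "n_meth", "n_unmeth"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}: non-integer {col!r} at line {line}")
        df[col] = converted.astype(np.int64)
    unknown = ~df["context"].isin(CONTEXTS)
    if unknown.any():
        line = int(np.flatnonzero(unknown.to_numpy())[0]) + 1
        raise ValueError(
            f"{path}: unknown context {df['context'].iloc[line - 1]!r} at line {line}"
        )
    df["n_total"] = df["n_meth"] + df["n_unmeth"]
    return df[["chrom", "pos", "strand", "context", "n_meth", "n_total"]]


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "n_meth": pd.Series(dtype=np.int64),
            "n_total": pd.Series(dtype=np.int64),
        }
    )


SITE_KEY = ["chrom", "pos", "strand", "context"]


def pool_replicates(
    replicate_records: dict[str, pd.DataFrame],
    sample_sheet: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Sum read counts across an accession's biological replicates.

    ``sample_sheet`` needs columns ``accession`` and ``replicate``; each
    replicate id must map to exactly one accession.  The site universe of
    an accession is the union over its replicates; a site seen in only
    one replicate keeps that replicate's counts.
    """
    rep_to_acc = sample_sheet.groupby("replicate")["accession"].nunique()
    dupes = rep_to_acc[rep_to_acc > 1]
    if len(dupes):
        raise ValueError(
            f"replicates assigned to multiple accessions: {list(dupes.index)}"
        )
    mapping = sample_sheet.drop_duplicates("replicate").set_index("replicate")[
        "accession"
    ]
    pooled: dict[str, pd.DataFrame] = {}
    by_acc: dict[str, list[pd.DataFrame]] = {}
    for rep_id, recs in replicate_records.items():
        if rep_id not in mapping.index:
            raise ValueError(f"replicate {rep_id!r} absent from sample sheet")
        by_acc.setdefault(mapping[rep_id], []).append(recs)
    for acc, frames in by_acc.items():
        if len(frames) == 1:
            pooled[acc] = frames[0].copy()
            continue
        cat = pd.concat(frames, ignore_index=True)
        agg = (
            cat.groupby(SITE_KEY, sort=True, as_index=False)[["n_meth", "n_total"]]
            .sum()
        )
        pooled[acc] = agg
    return pooled


def filter_coverage(records: pd.DataFrame, min_reads: int = 3) -> pd.DataFrame:
    """Keep sites supported by strictly more than ``min_reads`` reads.

    Idempotent: a second application with the same threshold is a no-op.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    return records[records["n_total"] > min_reads].reset_index(drop=True)


@dataclass
class MethylationMatrix:
    """Sites x accessions methylation levels backed by pooled read counts.

    ``meth`` / ``total`` are (n_sites, n_accessions) count arrays; a cell
    is non-missing iff its pooled support exceeds ``min_reads``.  Keeping
    counts (not just ratios) lets region levels use the pooled-count
    convention sum(m)/sum(t).
    """

    sites: pd.DataFrame  # columns chrom, pos (1-based), strand, context
    meth: np.ndarray
    total: np.ndarray
    accessions: list[str]
    min_reads: int = 3
    _levels: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def levels(self) -> np.ndarray:
        """Per-cell level m/t, NaN where support <= min_reads."""
        if self._levels is None:
            with np.errstate(invalid="ignore", divide="ignore"):
                lv = self.meth / self.total
            lv = np.where(self.total > self.min_reads, lv, np.nan)
            object.__setattr__(self, "_levels", lv)
        return self._levels

    def accession_index(self, names) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.accessions)}
        try:
            return np.array([pos[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"accession {exc.args[0]!r} not in matrix") from exc

    def subset_context(self, context: str) -> "MethylationMatrix":
        mask = (self.sites["context"] == context).to_numpy()
        return MethylationMatrix(
            self.sites[mask].reset_index(drop=True),
            self.meth[mask],
            self.total[mask],
            list(self.accessions),
            self.min_reads,
        )

    def site_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of sites inside a 0-based half-open interval."""
        pos0 = self.sites["pos"].to_numpy() - 1
        return (
            (self.sites["chrom"].to_numpy() == chrom)
            & (pos0 >= start)
            & (pos0 < end)
        )


def build_methylation_matrix(
    accession_records: dict[str, pd.DataFrame],
    populations: dict[str, str] | None = None,
    contexts=CONTEXTS,
    min_fraction_present: float = 0.7,
    min_reads: int = 3,
) -> MethylationMatrix:
    """Assemble the level matrix from per-accession (replicate-pooled) records.

    A site is retained only if it is non-missing (support > ``min_reads``)
    in at least ``min_fraction_present`` of the accessions of *every*
    population; with ``populations=None`` all accessions form one group.
    """
    if not accession_records:
        raise ValueError("need at least one accession")
    accessions = sorted(accession_records)
    pieces = []
    for i, acc in enumerate(accessions):
        recs = accession_records[acc]
        recs = recs[recs["context"].isin(contexts)]
        pieces.append(
            recs[SITE_KEY + ["n_meth", "n_total"]].assign(_acc=i)
        )
    cat = pd.concat(pieces, ignore_index=True)
    site_df = (
        cat[SITE_KEY].drop_duplicates().sort_values(SITE_KEY).reset_index(drop=True)
    )
    site_id = site_df.reset_index().set_index(SITE_KEY)["index"]
    row = site_id.loc[list(map(tuple, cat[SITE_KEY].itertuples(index=False)))].to_numpy()
    n_sites, n_acc = len(site_df), len(accessions)
    meth = np.zeros((n_sites, n_acc), dtype=np.int64)
    total = np.zeros((n_sites, n_acc), dtype=np.int64)
    col = cat["_acc"].to_numpy()
    meth[row, col] = cat["n_meth"].to_numpy()
    total[row, col] = cat["n_total"].to_numpy()

    present = total > min_reads
    keep = np.ones(n_sites, dtype=bool)
    if populations is None:
        groups = {"all": accessions}
    else:
        groups = {}
        for acc in accessions:
            groups.setdefault(populations[acc], []).append(acc)
    for members in groups.values():
        idx = [accessions.index(a) for a in members]
        frac = present[:, idx].mean(axis=1)
        keep &= frac >= min_fraction_present
    if not keep.any():
        warnings.warn("no sites pass the presence filter; matrix is empty")
    return MethylationMatrix(
        site_df[keep].reset_index(drop=True),
        meth[keep],
        total[keep],
        accessions,
        min_reads,
    )


def region_methylation_level(
    matrix: MethylationMatrix,
    chrom: str,
    start: int,
    end: int,
    context: str | None = None,
    accessions=None,
) -> pd.Series:
    """Weighted methylation level sum(m)/sum(t) of a region per accession.

    Pools read counts over the region's covered sites (cells failing the
    support filter contribute nothing), which weights sites by coverage;
    this deliberately differs from the unweighted mean of site levels.
    Returns NaN for accessions with no covered site in the region.
    """
    if end <= start:
        raise ValueError("region must be non-empty ([start, end) half-open)")
    mask = matrix.site_mask(chrom, start, end)
    if context is not None:
        mask &= (matrix.sites["context"] == context).to_numpy()
    cols = (
        np.arange(len(matrix.accessions))
        if accessions is None
        else matrix.accession_index(accessions)
    )
    names = matrix.accessions if accessions is None else list(accessions)
    supported = matrix.total[mask][:, cols] > matrix.min_reads
    m = np.where(supported, matrix.meth[mask][:, cols], 0).sum(axis=0)
    t = np.where(supported, matrix.total[mask][:, cols], 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lv = np.where(t > 0, m / np.maximum(t, 1), np.nan)
    return pd.Series(lv, index=names, name=f"{chrom}:{start}-{end}")


def chromosome_window_levels(
    matrix: MethylationMatrix,
    chrom_lengths: dict[str, int],
    window: int = 500_000,
    accessions=None,
) -> pd.DataFrame:
    """Mean methylation in non-overlapping windows tiling each chromosome.

    The window mean is the average of site levels inside it, across the
    requested accessions; empty windows yield NaN.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    cols = (
        np.arange(len(matrix.accessions))
        if accessions is None
        else matrix.accession_index(accessions)
    )
    lv = matrix.levels[:, cols]
    site_mean = np.nanmean(lv, axis=1) if lv.size else np.array([])
    out = []
    pos0 = matrix.sites["pos"].to_numpy() - 1
    for chrom, length in chrom_lengths.items():
        on = matrix.sites["chrom"].to_numpy() == chrom
        for context in sorted(matrix.sites["context"].unique()):
            sel = on & (matrix.sites["context"] == context).to_numpy()
            p = pos0[sel]
            v = site_mean[sel]
            for start in range(0, length, window):
                end = min(start + window, length)
                inw = (p >= start) & (p < end)
                mean = float(np.nanmean(v[inw])) if inw.any() else np.nan
                out.append((chrom, start, end, context, mean))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "context", "level"])


@dataclass
class Metaprofile:
    """80-bin profile: 20 upstream-flank, 40 body, 20 downstream bins."""

    context: str
    label: str
    values: np.ndarray  # length 80, NaN where no data

    N_UP, N_BODY, N_DOWN = 20, 40, 20

    def __post_init__(self):
        assert len(self.values) == self.N_UP + self.N_BODY + self.N_DOWN


def feature_metaprofile(
    matrix: MethylationMatrix,
    features: pd.DataFrame,
    context: str,
    flank: int = 2_000,
    accessions=None,
    label: str = "",
) -> Metaprofile:
    """Average methylation around stranded features in 20/40/20 bins.

    Sites are first averaged across accessions, then mapped to fractional
    coordinates along flank-2kb / body / flank-2kb of each feature (minus-
    strand features are reversed so bin 1 is always 5'-most), and finally
    averaged over features per bin.  Body bins scale with feature length,
    so short features are still binned fractionally.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    sub = matrix.subset_context(context)
    cols = (
        np.arange(len(sub.accessions))
        if accessions is None
        else sub.accession_index(accessions)
    )
    site_mean = np.nanmean(sub.levels[:, cols], axis=1) if sub.n_sites else np.array([])
    pos0 = sub.sites["pos"].to_numpy() - 1
    chroms = sub.sites["chrom"].to_numpy()
    n_up, n_body, n_down = Metaprofile.N_UP, Metaprofile.N_BODY, Metaprofile.N_DOWN
    nbins = n_up + n_body + n_down
    sums = np.zeros(nbins)
    counts = np.zeros(nbins)
    for feat in features.itertuples(index=False):
        length = feat.end - feat.start
        if length <= 0:
            continue
        sel = (chroms == feat.chrom) & (pos0 >= feat.start - flank) & (
            pos0 < feat.end + flank
        )
        if not sel.any():
            continue
        p = pos0[sel]
        v = site_mean[sel]
        # u: distance from the 5'-most base of the extended interval
        if feat.strand == "-":
            u = (feat.end + flank - 1) - p
        else:
            u = p - (feat.start - flank)
        binidx = np.empty(len(u), dtype=int)
        up = u < flank
        body = (u >= flank) & (u < flank + length)
        down = u >= flank + length
        binidx[up] = (u[up] / flank * n_up).astype(int)
        binidx[body] = n_up + ((u[body] - flank) / length * n_body).astype(int)
        binidx[down] = (
            n_up + n_body + ((u[down] - flank - length) / flank * n_down).astype(int)
        )
        binidx = np.clip(binidx, 0, nbins - 1)
        ok = ~np.isnan(v)
        # average within feature per bin, then accumulate across features
        feat_sum = np.bincount(binidx[ok], weights=v[ok], minlength=nbins)
        feat_n = np.bincount(binidx[ok], minlength=nbins)
        has = feat_n > 0
        sums[has] += feat_sum[has] / feat_n[has]
        counts[has] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return Metaprofile(context=context, label=label, values=values)


def accession_genome_means(
    matrix: MethylationMatrix, contexts=CONTEXTS
) -> pd.DataFrame:
    """Genome-wide weighted level sum(m)/sum(t) per accession per context."""
    rows = {}
    for ctx in contexts:
        sub = matrix.subset_context(ctx)
        supported = sub.total > sub.min_reads
        m = np.where(supported, sub.meth, 0).sum(axis=0)
        t = np.where(supported, sub.total, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[ctx] = np.where(t > 0, m / np.maximum(t, 1), np.nan)
    return pd.DataFrame(rows, index=matrix.accessions)


def population_level_summary(
    matrix: MethylationMatrix,
    sample_sheet: pd.DataFrame,
    contexts=("CG", "CHG", "CHH"),
) -> dict:
    """Population mean levels and pairwise tests on per-accession means.

    Population sizes generally differ, so the paired t-test is run after
    pairing accessions by the rank of their genome-wide mean within each
    population and truncating to the smaller n; the unpaired Welch test is
    reported alongside.  Zero-variance paired differences are degenerate:
    p is reported as 1.0 when the common difference is 0 and 0.0 otherwise,
    with a warning.
    """
    means = accession_genome_means(matrix, contexts)
    pops = sample_sheet.drop_duplicates("accession").set_index("accession")[
        "population"
    ]
    labels = list(dict.fromkeys(pops.loc[matrix.accessions]))
    members = {
        lab: [a for a in matrix.accessions if pops[a] == lab] for lab in labels
    }
    for lab, mem in members.items():
        if len(mem) < 2:
            raise ValueError(f"population {lab!r} has fewer than 2 accessions")
    out = {"population_means": {}, "tests": []}
    for ctx in contexts:
        out["population_means"][ctx] = {
            lab: float(np.nanmean(means.loc[mem, ctx])) for lab, mem in members.items()
        }
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            la, lb = labels[i], labels[j]
            for ctx in contexts:
                a = np.sort(means.loc[members[la], ctx].dropna().to_numpy())
                b = np.sort(means.loc[members[lb], ctx].dropna().to_numpy())
                n = min(len(a), len(b))
                if len(a) != len(b):
                    warnings.warn(
                        f"{la} vs {lb}: unequal sizes, pairing truncated to n={n}"
                    )
                d = b[:n] - a[:n]
                if np.allclose(d.std(ddof=1) if n > 1 else 0.0, 0.0):
                    if np.allclose(d, 0):
                        t_stat, p_paired = 0.0, 1.0
                    else:
                        warnings.warn(
                            f"{la} vs {lb} ({ctx}): zero-variance paired differences"
                        )
                        t_stat = np.inf * np.sign(d.mean())
                        p_paired = 0.0
                else:
                    t_stat, p_paired = stats.ttest_rel(b[:n], a[:n])
                w_stat, p_welch = stats.ttest_ind(b, a, equal_var=False)
                out["tests"].append(
                    {
                        "pop_a": la,
                        "pop_b": lb,
                        "context": ctx,
                        "n_pairs": int(n),
                        "t_paired": float(t_stat),
                        "p_paired": float(p_paired),
                        "t_welch": float(w_stat),
                        "p_welch": float(p_welch),
                    }
                )
    return out


def context_site_spectrum(
    matrix: MethylationMatrix, accessions=None
) -> pd.DataFrame:
    """10-bin frequency spectrum of per-site mean levels per context.

    Bins [0,0.1), ..., [0.9,1.0] with the last bin closed; frequencies
    sum to 1 within each context.
    """
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    cols = (
        np.arange(len(matrix.accessions))
        if accessions is None
        else matrix.accession_index(accessions)
    )
    site_mean = np.nanmean(matrix.levels[:, cols], axis=1)
    edges = np.linspace(0.0, 1.0, 11)
    out = []
    for ctx in sorted(matrix.sites["context"].unique()):
        sel = (matrix.sites["context"] == ctx).to_numpy()
        v = site_mean[sel]
        v = v[~np.isnan(v)]
        if len(v) == 0:
            continue
        hist, _ = np.histogram(v, bins=edges)  # numpy closes the last bin
        freq = hist / hist.sum()
        for k in range(10):
            out.append((ctx, edges[k], edges[k + 1], freq[k]))
    return pd.DataFrame(out, columns=["context", "lo", "hi", "frequency"])
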