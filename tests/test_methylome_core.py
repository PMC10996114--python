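"""Cytosine-report parsing, pooling, filtering, matrix and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popmeth import methylome_core as mc

from conftest import matrix_from_levels


def write_report(tmp_path, lines, name="r.txt"):
    p = tmp_path / name
    p.write_text("".join(line + "\n" for line in lines))
    return p


class TestReadCytosineReport:
    def test_seven_column_line(self, tmp_path):
        p = write_report(tmp_path, ["chr1\t100\t+\t3\t7\tCG\tCGA"])
        df = mc.read_cytosine_report(p)
        rec = df.iloc[0]
        assert (rec.chrom, rec.pos, rec.strand, rec.context) == ("chr1", 100, "+", "CG")
        assert rec.n_meth == 3 and rec.n_total == 10

    def test_zero_coverage_site_kept_at_parse_stage(self, tmp_path):
        p = write_report(tmp_path, ["chr1\t5\t-\t0\t0\tCHH\tCAT"])
        df = mc.read_cytosine_report(p)
        assert df.iloc[0].n_total == 0

    def test_order_preserved(self, tmp_path):
        rng = np.random.default_rng(0)
        pos = rng.choice(100_000, size=1_000, replace=False)
        lines = [f"chr1\t{p}\t+\t1\t1\tCG\tCGA" for p in pos]
        df = mc.read_cytosine_report(write_report(tmp_path, lines))
        assert len(df) == 1_000
        assert (df["pos"].to_numpy() == pos).all()

    def test_empty_file(self, tmp_path):
        assert len(mc.read_cytosine_report(write_report(tmp_path, []))) == 0

    def test_malformed_count_reports_line_number(self, tmp_path):
        p = write_report(
            tmp_path, ["chr1\t1\t+\t1\t1\tCG\tCGA", "chr1\t2\t+\tx\t1\tCG\tCGA"]
        )
        with pytest.raises(ValueError, match="line 2"):
            mc.read_cytosine_report(p)

    def test_unknown_context_rejected(self, tmp_path):
        p = write_report(tmp_path, ["chr1\t1\t+\t1\t1\tXX\tnnn"])
        with pytest.raises(ValueError, match="context"):
            mc.read_cytosine_report(p)


def records(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    )


class TestPoolReplicates:
    sheet = pd.DataFrame(
        {"accession": ["a", "a"], "replicate": ["a_rep1", "a_rep2"]}
    )

    def test_counts_sum_across_replicates(self):
        r1 = records([("chr1", 10, "+", "CG", 3, 10)])
        r2 = records([("chr1", 10, "+", "CG", 2, 10)])
        pooled = mc.pool_replicates({"a_rep1": r1, "a_rep2": r2}, self.sheet)
        row = pooled["a"].iloc[0]
        assert (row.n_meth, row.n_total) == (5, 20)

    def test_site_in_one_replicate_keeps_its_counts(self):
        r1 = records([("chr1", 10, "+", "CG", 3, 10), ("chr1", 50, "+", "CG", 4, 8)])
        r2 = records([("chr1", 10, "+", "CG", 2, 10)])
        pooled = mc.pool_replicates({"a_rep1": r1, "a_rep2": r2}, self.sheet)
        only = pooled["a"].set_index("pos").loc[50]
        assert (only.n_meth, only.n_total) == (4, 8)

    def test_single_replicate_is_identity(self):
        r1 = records([("chr1", 10, "+", "CG", 3, 10)])
        sheet = pd.DataFrame({"accession": ["a"], "replicate": ["a_rep1"]})
        pooled = mc.pool_replicates({"a_rep1": r1}, sheet)
        pd.testing.assert_frame_equal(pooled["a"], r1)

    def test_replicate_in_two_accessions_rejected(self):
        sheet = pd.DataFrame(
            {"accession": ["a", "b"], "replicate": ["rep1", "rep1"]}
        )
        with pytest.raises(ValueError, match="multiple accessions"):
            mc.pool_replicates({"rep1": records([])}, sheet)


class TestFilterCoverage:
    @pytest.mark.parametrize(
        "n_total,min_reads,kept",
        [(3, 3, False), (4, 3, True), (0, 0, False), (1, 0, True)],
    )
    def test_strict_threshold(self, n_total, min_reads, kept):
        df = records([("chr1", 1, "+", "CG", 0, n_total)])
        out = mc.filter_coverage(df, min_reads)
        assert (len(out) == 1) == kept

    def test_idempotent(self):
        df = records(
            [("chr1", p, "+", "CG", 1, t) for p, t in [(1, 2), (2, 10), (3, 4)]]
        )
        once = mc.filter_coverage(df, 3)
        twice = mc.filter_coverage(once, 3)
        pd.testing.assert_frame_equal(once, twice)


class TestBuildMatrix:
    def test_levels_and_missingness(self):
        acc = {
            "a": records([("chr1", 10, "+", "CG", 5, 10)]),
            "b": records([("chr1", 10, "+", "CG", 5, 10)]),
        }
        m = mc.build_methylation_matrix(acc, min_fraction_present=0.5)
        assert m.n_sites == 1
        assert np.allclose(m.levels, 0.5)

    def test_presence_threshold_per_population(self):
        # the site is missing in half of population 'p'; 0.7 rule drops it
        acc = {
            "a": records([("chr1", 10, "+", "CG", 5, 10)]),
            "b": records([]),
            "c": records([("chr1", 10, "+", "CG", 5, 10)]),
            "d": records([("chr1", 10, "+", "CG", 5, 10)]),
        }
        pops = {"a": "p", "b": "p", "c": "q", "d": "q"}
        dropped = mc.build_methylation_matrix(
            acc, populations=pops, min_fraction_present=0.7
        )
        assert dropped.n_sites == 0
        kept = mc.build_methylation_matrix(
            acc, populations=pops, min_fraction_present=0.5
        )
        assert kept.n_sites == 1

    def test_no_cell_with_support_below_threshold(self, small_matrix):
        lv = small_matrix.levels
        low = small_matrix.total <= small_matrix.min_reads
        assert np.isnan(lv[low]).all()


class TestRegionLevel:
    def make(self):
        sites = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [100, 200],
                "strand": ["+", "+"],
                "context": ["CG", "CG"],
            }
        )
        m = mc.MethylationMatrix(
            sites=sites,
            meth=np.array([[1], [9]]),
            total=np.array([[4], [16]]),
            accessions=["a"],
            min_reads=3,
        )
        return m

    def test_weighted_not_unweighted(self):
        m = self.make()
        lv = mc.region_methylation_level(m, "chr1", 0, 1000)
        # pooled 10/20 = 0.5, not the unweighted mean (0.25 + 0.5625)/2
        assert lv["a"] == pytest.approx(0.5)
        assert lv["a"] != pytest.approx((1 / 4 + 9 / 16) / 2)

    def test_all_unmethylated_gives_zero(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [10], "strand": ["+"], "context": ["CG"]}
        )
        m = mc.MethylationMatrix(sites, np.array([[0]]), np.array([[8]]), ["a"])
        assert mc.region_methylation_level(m, "chr1", 0, 100)["a"] == 0.0

    def test_region_without_sites_is_missing(self):
        m = self.make()
        assert np.isnan(mc.region_methylation_level(m, "chr2", 0, 100)["a"])

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            mc.region_methylation_level(self.make(), "chr1", 100, 100)

    def test_whole_chromosome_equals_pooled_counts(self, small_matrix):
        m = small_matrix.subset_context("CG")
        on = (m.sites["chrom"] == "chr1").to_numpy()
        sup = m.total[on] > m.min_reads
        expected = np.where(sup, m.meth[on], 0).sum(axis=0) / np.where(
            sup, m.total[on], 0
        ).sum(axis=0)
        got = mc.region_methylation_level(
            small_matrix, "chr1", 0, 10**9, context="CG"
        ).to_numpy()
        np.testing.assert_allclose(got, expected)


class TestChromosomeWindows:
    def test_tiling_and_constant_level(self):
        sites = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, 1_000_001, 10_000),
                "strand": "+",
                "context": "CG",
            }
        )
        lv = np.full((len(sites), 2), 0.3)
        m = matrix_from_levels(lv, sites, ["a", "b"], depth=10)
        out = mc.chromosome_window_levels(m, {"chr1": 1_000_000}, window=500_000)
        assert len(out) == 2
        assert np.allclose(out["level"], 0.3)

    def test_empty_window_is_missing(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "strand": ["+"], "context": ["CG"]}
        )
        m = matrix_from_levels(np.array([[0.5]]), sites, ["a"])
        out = mc.chromosome_window_levels(m, {"chr1": 1_000_000}, window=500_000)
        assert np.isnan(out["level"].iloc[1])


class TestMetaprofile:
    def uniform_matrix(self, level=0.4):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(20_000, 3_000, replace=False)) + 1
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "strand": "+", "context": "CG"}
        )
        lv = np.full((len(sites), 1), level)
        return matrix_from_levels(lv, sites, ["a"])

    def test_uniform_signal_fills_all_bins(self):
        m = self.uniform_matrix()
        feats = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "start": [8_000], "end": [12_000], "strand": ["+"]}
        )
        prof = mc.feature_metaprofile(m, feats, "CG")
        assert len(prof.values) == 80
        np.testing.assert_allclose(prof.values, 0.4, atol=1e-9)

    def test_minus_strand_flips_flanks(self):
        # hypermethylation physically right of the gene = 3' flank on + strand
        pos = np.arange(1, 20_001, 10)
        level = np.where(pos > 12_000, 0.8, 0.2)
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "strand": "+", "context": "CG"}
        )
        m = matrix_from_levels(level[:, None], sites, ["a"])
        plus = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "start": [8_000], "end": [12_000], "strand": ["+"]}
        )
        minus = plus.assign(strand="-")
        p_plus = mc.feature_metaprofile(m, plus, "CG").values
        p_minus = mc.feature_metaprofile(m, minus, "CG").values
        assert p_plus[60:].mean() > 0.7  # downstream block elevated
        assert p_minus[:20].mean() > 0.7  # flipped to upstream block
        # strand flip of a profile reverses the bin order
        np.testing.assert_allclose(p_plus, p_minus[::-1], atol=1e-9)

    def test_strand_symmetric_signal_invariant_under_flip(self, small_matrix, small_dataset):
        genes = small_dataset.annotation.genes
        p1 = mc.feature_metaprofile(small_matrix, genes, "CG").values
        p2 = mc.feature_metaprofile(
            small_matrix,
            genes.assign(strand=genes["strand"].map({"+": "-", "-": "+"})),
            "CG",
        ).values
        # flipping every strand reverses the average profile
        np.testing.assert_allclose(p1, p2[::-1], atol=1e-12)


class TestPopulationSummary:
    def summary_for(self, vals_a, vals_b):
        n = len(vals_a)
        sites = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [10], "strand": ["+"], "context": ["CG"]}
        )
        levels = np.array([vals_a + vals_b])
        accs = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        m = matrix_from_levels(levels, sites, accs)
        sheet = pd.DataFrame(
            {"accession": accs, "population": ["A"] * n + ["B"] * n}
        )
        return mc.population_level_summary(m, sheet, contexts=("CG",))

    def test_identical_populations(self):
        out = self.summary_for([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        t = out["tests"][0]
        assert t["t_paired"] == 0.0 and t["p_paired"] == 1.0

    def test_constant_shift_degenerates_to_p_zero(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out = self.summary_for([0.2, 0.3, 0.4], [0.3, 0.4, 0.5])
        assert out["tests"][0]["p_paired"] == 0.0

    def test_paired_t_matches_textbook_formula(self):
        # sorted paired differences {0.08, 0.09, 0.10, 0.11, 0.12}:
        # mean 0.1, sd 0.0158114, t = 0.1 / (sd / sqrt(5)) = 14.1421
        a = [0.20, 0.30, 0.40, 0.50, 0.60]
        b = [0.28, 0.39, 0.50, 0.61, 0.72]
        out = self.summary_for(a, b)
        t = out["tests"][0]
        assert t["t_paired"] == pytest.approx(14.1421356, rel=1e-4)
        assert t["p_paired"] == pytest.approx(
            2 * stats.t.sf(14.1421356, df=4), rel=1e-3
        )


class TestSiteSpectrum:
    def test_last_bin_closed(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [1, 2, 3], "strand": "+", "context": "CG"}
        )
        m = matrix_from_levels(np.ones((3, 1)), sites, ["a"])
        spec = mc.context_site_spectrum(m)
        assert spec["frequency"].iloc[-1] == 1.0

    def test_uniform_grid_fills_bins_equally(self):
        levels = np.arange(0.05, 1.0, 0.1)[:, None]
        sites = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, len(levels) + 1),
                "strand": "+",
                "context": "CG",
            }
        )
        m = matrix_from_levels(levels, sites, ["a"])
        spec = mc.context_site_spectrum(m)
        np.testing.assert_allclose(spec["frequency"], 0.1)

    def test_chh_skewed_toward_unmethylation(self, small_matrix):
        spec = mc.context_site_spectrum(small_matrix)
        chh = spec[spec["context"] == "CHH"].reset_index(drop=True)
        assert chh["frequency"].sum() == pytest.approx(1.0)
        # modal bin in the lowest fifth, bulk of sites below 0.2
        assert chh["frequency"].idxmax() <= 1
        assert chh["frequency"].iloc[:2].sum() > 0.5
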