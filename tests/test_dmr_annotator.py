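"""Interval algebra, composition, coevolution correlation and PCA."""

import numpy as np
import pandas as pd
import pytest

from popmeth import dmr_annotator as da
from popmeth.dmr_caller import Dmr

from conftest import matrix_from_levels


def dmr(chrom, start, end, context="CG", delta=0.4):
    return Dmr(
        chrom, start, end, context, 10, 0.2, 0.2 + delta, delta, 1e-4, 1e-3,
        "hyper" if delta > 0 else "hypo",
    )


class TestContextOverlap:
    def test_one_bp_overlap_groups_both(self):
        g = da.classify_context_overlap(
            [dmr("chr1", 100, 200)], [dmr("chr1", 150, 250, "CHG")]
        )
        assert len(g.o_pairs) == 1
        assert g.u_cg == [] and g.u_chg == []

    def test_bookended_regions_are_unique(self):
        g = da.classify_context_overlap(
            [dmr("chr1", 100, 200)], [dmr("chr1", 200, 300, "CHG")]
        )
        assert g.o_pairs == []
        assert len(g.u_cg) == 1 and len(g.u_chg) == 1

    def test_empty_chg_makes_all_cg_unique(self):
        g = da.classify_context_overlap([dmr("chr1", 0, 50)], [])
        assert len(g.u_cg) == 1 and not g.o_pairs

    def test_partition_conserves_counts(self):
        rng = np.random.default_rng(0)
        cg = [dmr("chr1", int(s), int(s) + 80) for s in rng.integers(0, 5_000, 40)]
        chg = [
            dmr("chr1", int(s), int(s) + 80, "CHG")
            for s in rng.integers(0, 5_000, 40)
        ]
        g = da.classify_context_overlap(cg, chg)
        assert len(g.o_cg) + len(g.u_cg) == len(cg)
        assert len(g.o_chg) + len(g.u_chg) == len(chg)
        assert not ({id(d) for d in g.o_cg} & {id(d) for d in g.u_cg})


def toy_annotation():
    genes = pd.DataFrame(
        [("g1", "chr1", 10_000, 13_000, "+")],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    exons = pd.DataFrame(
        [("g1", "chr1", 10_000, 11_000), ("g1", "chr1", 12_000, 13_000)],
        columns=["gene_id", "chrom", "start", "end"],
    )
    tes = pd.DataFrame(
        [("chr1", 20_000, 21_000, "Gypsy")],
        columns=["chrom", "start", "end", "te_class"],
    )
    return da.AnnotationSet(genes, exons, tes, {"chr1": 50_000})


class TestGenomicComposition:
    def test_region_inside_exon(self):
        ann = toy_annotation()
        frac = da.genomic_composition([("chr1", 10_100, 10_200)], ann)
        assert frac["exon"] == 1.0

    def test_half_exon_half_te(self):
        ann = toy_annotation()
        # 100 bp: 50 in the exon end, 50 in raw intergenic? use TE region
        frac = da.genomic_composition(
            [("chr1", 12_950, 13_000), ("chr1", 20_000, 20_050)], ann
        )
        assert frac["exon"] == pytest.approx(0.5)
        assert frac["te"] == pytest.approx(0.5)

    def test_intron_outranks_te_by_default(self):
        ann = toy_annotation()
        ann.tes.loc[len(ann.tes)] = ("chr1", 11_200, 11_800, "Copia")
        default = da.genomic_composition([("chr1", 11_200, 11_800)], ann)
        assert default["intron"] == 1.0
        flipped = da.genomic_composition(
            [("chr1", 11_200, 11_800)], ann, te_over_intron=True
        )
        assert flipped["te"] == 1.0

    def test_split_invariance(self):
        ann = toy_annotation()
        whole = da.genomic_composition([("chr1", 9_000, 15_000)], ann)
        halves = da.genomic_composition(
            [("chr1", 9_000, 12_000), ("chr1", 12_000, 15_000)], ann
        )
        for k in whole:
            assert whole[k] == pytest.approx(halves[k])

    def test_fractions_sum_to_one_genomewide(self):
        ann = toy_annotation()
        frac = da.genomic_composition([("chr1", 0, 50_000)], ann)
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_region_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            da.genomic_composition([("chr1", 49_000, 60_000)], toy_annotation())
        with pytest.raises(ValueError):
            da.genomic_composition([("chrX", 0, 10)], toy_annotation())


class TestGenesNearRegions:
    genes = pd.DataFrame(
        [("plus", "chr1", 10_000, 13_000, "+"), ("minus", "chr1", 10_000, 13_000, "-")],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )

    def test_five_prime_flank_is_upstream_for_plus_strand(self):
        # region 1.5 kb 5' of the plus-strand TSS
        pairs = da.genes_near_regions(
            [("chr1", 8_400, 8_600)], self.genes.iloc[[0]], region_ids=["r"]
        )
        assert pairs.iloc[0].location == "upstream"

    def test_same_region_is_downstream_for_minus_strand(self):
        pairs = da.genes_near_regions(
            [("chr1", 8_400, 8_600)], self.genes.iloc[[1]], region_ids=["r"]
        )
        assert pairs.iloc[0].location == "downstream"

    def test_region_beyond_flank_unpaired(self):
        pairs = da.genes_near_regions(
            [("chr1", 6_000, 6_500)], self.genes, region_ids=["r"]
        )
        assert pairs.empty

    def test_body_outranks_flank(self):
        pairs = da.genes_near_regions(
            [("chr1", 9_500, 10_500)], self.genes.iloc[[0]], region_ids=["r"]
        )
        assert pairs.iloc[0].location == "body"


class TestSharedRegions:
    def test_identical_sets(self):
        s = [("chr1", 0, 100), ("chr2", 50, 80)]
        out = da.shared_regions(s, list(s))
        assert out["jaccard_bp"] == 1.0
        assert out["n_a_overlapping"] == 2

    def test_disjoint_sets(self):
        out = da.shared_regions([("chr1", 0, 10)], [("chr1", 20, 30)])
        assert out["n_a_overlapping"] == 0 and out["jaccard_bp"] == 0.0

    def test_partial_overlap_jaccard(self):
        out = da.shared_regions([("chr1", 0, 100)], [("chr1", 50, 150)])
        assert out["jaccard_bp"] == pytest.approx(1 / 3)


class TestCoevolutionCorrelation:
    def test_perfectly_linear_levels_give_r_one(self):
        # 6 loci, CG level == CHG level at each locus
        rows = []
        levels = []
        for k, lv in enumerate([0.1, 0.25, 0.4, 0.55, 0.7, 0.85]):
            for ctx, off in [("CG", 0), ("CHG", 5)]:
                rows.append(("chr1", 1_000 * k + 1 + off, "+", ctx))
                levels.append([lv, lv, lv])
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context"])
        m = matrix_from_levels(np.array(levels), sites, ["x", "y", "z"], depth=1000)
        cg = [dmr("chr1", 1_000 * k, 1_000 * k + 10) for k in range(6)]
        chg = [dmr("chr1", 1_000 * k + 3, 1_000 * k + 13, "CHG") for k in range(6)]
        groups = da.classify_context_overlap(cg, chg)
        out = da.coevolution_correlation(groups, m, {"all": ["x", "y", "z"]})
        assert out["o_cg_chg"]["pooled"]["r"] == pytest.approx(1.0, abs=1e-6)

    def test_planted_coupling_recovered(self, small_dataset, small_matrix, small_populations):
        truth = small_dataset.truth
        cg = [
            dmr(t["chrom"], t["start"], t["end"])
            for t in truth.dmr_regions
            if t["context"] == "CG"
        ]
        chg = [
            dmr(t["chrom"], t["start"], t["end"], "CHG")
            for t in truth.dmr_regions
            if t["context"] == "CHG"
        ]
        groups = da.classify_context_overlap(cg, chg)
        members = {}
        for acc, pop in small_populations.items():
            members.setdefault(pop, []).append(acc)
        out = da.coevolution_correlation(groups, small_matrix, members)
        assert out["o_cg_chg"]["pooled"]["r"] > 0.8


class TestMethylationPca:
    def test_duplicated_accession_identical_coordinates(self):
        rng = np.random.default_rng(0)
        levels = rng.uniform(0, 1, size=(50, 3))
        levels = np.hstack([levels, levels[:, [0]]])  # duplicate first accession
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, 51), "strand": "+", "context": "CG"}
        )
        m = matrix_from_levels(levels, sites, ["a", "b", "c", "a2"], depth=10_000)
        coords, _ = da.methylation_pca(m, "CG")
        np.testing.assert_allclose(
            coords.loc["a"].to_numpy(), coords.loc["a2"].to_numpy(), atol=1e-6
        )

    def test_constant_matrix_all_zero(self):
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, 21), "strand": "+", "context": "CG"}
        )
        m = matrix_from_levels(np.full((20, 4), 0.5), sites, list("abcd"))
        coords, evr = da.methylation_pca(m, "CG")
        assert np.allclose(coords.to_numpy(), 0)
        assert np.allclose(evr, 0)

    def test_too_few_accessions_rejected(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [1], "strand": ["+"], "context": ["CG"]}
        )
        m = matrix_from_levels(np.array([[0.1, 0.9]]), sites, ["a", "b"])
        with pytest.raises(ValueError):
            da.methylation_pca(m, "CG")

    def test_improved_population_separates(self, small_matrix, small_populations):
        """Stage effects isolate the improved accessions beyond label chance."""
        from sklearn.metrics import silhouette_score

        coords, _ = da.methylation_pca(small_matrix, "CG")
        labels = np.array(
            [small_populations[a] == "improved" for a in coords.index]
        )
        obs = silhouette_score(coords.to_numpy(), labels)
        rng = np.random.default_rng(0)
        perms = [
            silhouette_score(coords.to_numpy(), rng.permutation(labels))
            for _ in range(99)
        ]
        p = (1 + sum(s >= obs for s in perms)) / 100
        assert p < 0.05


class TestReaders:
    def test_gff3_roundtrip(self, tmp_path, small_dataset):
        from popmeth.synthetic_data import _write_gff3

        path = tmp_path / "genes.gff3"
        _write_gff3(
            small_dataset.annotation.genes, small_dataset.annotation.exons, path
        )
        genes, exons = da.read_gff3_genes(path)
        pd.testing.assert_frame_equal(
            genes.sort_values("gene_id").reset_index(drop=True),
            small_dataset.annotation.genes.sort_values("gene_id").reset_index(
                drop=True
            ),
        )
        assert len(exons) == len(small_dataset.annotation.exons)

    def test_exon_outside_gene_rejected(self):
        genes = pd.DataFrame(
            [("g1", "chr1", 100, 200, "+")],
            columns=["gene_id", "chrom", "start", "end", "strand"],
        )
        exons = pd.DataFrame(
            [("g1", "chr1", 150, 250)], columns=["gene_id", "chrom", "start", "end"]
        )
        with pytest.raises(ValueError):
            da.AnnotationSet(genes, exons, pd.DataFrame(columns=["chrom", "start", "end", "te_class"]), {"chr1": 1_000})
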