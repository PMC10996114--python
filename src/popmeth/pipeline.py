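"""End-to-end orchestration: simulate -> methylomes -> DMRs -> sweeps ->
meQTL -> annotation -> expression correlation, with a machine-readable
run report.

The two comparisons follow the domestication series: (wild, landrace) is
'domestication' and (landrace, improved) is 'improvement'; hyper always
means the later stage gained methylation.  Every threshold used is
echoed into the report, and :func:`validate_report` checks the report's
internal bookkeeping identities (totals add up, local + distal =
significant clumped associations, composition fractions sum to 1).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import dmr_annotator, dmr_caller, expr_corr, meqtl, methylome_core, popgen_scan
from .synthetic_data import SimulationConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

COMPARISONS = {
    "domestication": ("wild", "landrace"),
    "improvement": ("landrace", "improved"),
}
DMR_CONTEXTS = ("CG", "CHG")


class RunParams(BaseModel):
    """All analysis thresholds, with the field-standard defaults."""

    model_config = ConfigDict(extra="forbid")

    min_reads: int = 3
    min_fraction_present: float = 0.7
    max_gap: int = 300
    min_sites: int = 8
    min_delta: float = 0.25
    q_cut: float = 0.01
    window: int = 10_000
    step: int = 1_000
    top_fraction: float = 0.10
    alpha: float = 0.01
    r2_max: float = 0.25
    local_dist: int = 1_000_000
    flank: int = 2_000
    maf_min: float = 0.05
    max_missing: float = 0.7
    n_genotype_pcs: int = 2


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    simulate: dict = {}
    params: RunParams = RunParams()


def load_workspace(outdir) -> dict:
    """Load a written dataset directory back into in-memory structures."""
    outdir = Path(outdir)
    sheet = pd.read_csv(outdir / "samples.tsv", sep="\t")
    replicate_records = {
        row.replicate: methylome_core.read_cytosine_report(outdir / row.file)
        for row in sheet.itertuples(index=False)
    }
    chrom_lengths = {}
    with open(outdir / "chrom_lengths.tsv") as fh:
        for line in fh:
            chrom, length = line.split()
            chrom_lengths[chrom] = int(length)
    genes, exons = dmr_annotator.read_gff3_genes(outdir / "annotation" / "genes.gff3")
    tes = dmr_annotator.read_bed_tes(outdir / "annotation" / "tes.bed")
    annotation = dmr_annotator.AnnotationSet(
        genes=genes, exons=exons, tes=tes, chrom_lengths=chrom_lengths
    )
    accessions = list(dict.fromkeys(sheet["accession"]))
    truth_path = outdir / "truth.json"
    return {
        "sample_sheet": sheet,
        "replicate_records": replicate_records,
        "accessions": accessions,
        "populations": dict(
            zip(sheet["accession"], sheet["population"])
        ),
        "chrom_lengths": chrom_lengths,
        "annotation": annotation,
        "expression": expr_corr.read_expression(outdir / "expression.tsv"),
        "vcf_path": outdir / "genotypes.vcf",
        "truth": json.loads(truth_path.read_text()) if truth_path.exists() else None,
    }


def stage_methylome(workspace: dict, params: RunParams):
    """Pool replicates, filter coverage, and build the level matrix."""
    pooled = methylome_core.pool_replicates(
        workspace["replicate_records"], workspace["sample_sheet"]
    )
    pooled = {
        acc: methylome_core.filter_coverage(recs, params.min_reads)
        for acc, recs in pooled.items()
    }
    matrix = methylome_core.build_methylation_matrix(
        pooled,
        populations=workspace["populations"],
        min_fraction_present=params.min_fraction_present,
        min_reads=params.min_reads,
    )
    summary = methylome_core.population_level_summary(
        matrix, workspace["sample_sheet"]
    )
    return matrix, summary


def stage_dmr(matrix, populations: dict, params: RunParams) -> dict:
    """Call DMRs for both comparisons in the CG and CHG contexts."""
    calls = {}
    for comp, (pop_a, pop_b) in COMPARISONS.items():
        calls[comp] = {}
        for ctx in DMR_CONTEXTS:
            calls[comp][ctx] = dmr_caller.call_dmrs(
                matrix,
                populations,
                pop_a,
                pop_b,
                ctx,
                max_gap=params.max_gap,
                min_sites=params.min_sites,
                min_delta=params.min_delta,
                q_cut=params.q_cut,
            )
    return calls


def stage_sweep(gm, populations: dict, chrom_lengths: dict, params: RunParams):
    """Windowed pi / F_ST for each comparison plus joint top-decile DSRs."""
    members = {}
    for acc, pop in populations.items():
        members.setdefault(pop, []).append(acc)
    out = {}
    for comp, (pop_a, pop_b) in COMPARISONS.items():
        pi_a = popgen_scan.window_diversity(
            gm, members[pop_a], chrom_lengths, params.window, params.step
        )
        pi_b = popgen_scan.window_diversity(
            gm, members[pop_b], chrom_lengths, params.window, params.step
        )
        fst = popgen_scan.window_fst(
            gm, members[pop_a], members[pop_b], chrom_lengths, params.window, params.step
        )
        windows = pi_a.rename(columns={"pi": "pi_ancestral"})
        windows["pi_derived"] = pi_b["pi"]
        windows["fst"] = fst["fst"]
        thresholds, regions = popgen_scan.sweep_scan(
            windows, comparison=comp, top_fraction=params.top_fraction
        )
        out[comp] = {"windows": windows, "thresholds": thresholds, "regions": regions}
    return out


def dmr_trait_levels(matrix, dmrs_by_id: dict) -> pd.DataFrame:
    """DMR x accession weighted methylation levels (the meQTL traits)."""
    rows = {}
    for dmr_id, d in dmrs_by_id.items():
        rows[dmr_id] = methylome_core.region_methylation_level(
            matrix, d.chrom, d.start, d.end, context=d.context
        )
    return pd.DataFrame(rows).T


def stage_meqtl(matrix, gm, calls: dict, params: RunParams):
    """Transform DMR traits, fit per-trait nulls, scan, clump, classify."""
    dmrs_by_id = {}
    for comp, by_ctx in calls.items():
        for ctx, dmrs in by_ctx.items():
            for k, d in enumerate(dmrs):
                dmrs_by_id[f"{comp[:3]}_{ctx}_{k:04d}"] = d
    if not dmrs_by_id:
        return {
            "n_traits": 0,
            "threshold": meqtl.bonferroni_threshold(max(gm.n_snps, 1), params.alpha),
            "associations": [],
            "significant": [],
            "pure_fraction": np.nan,
            "kinship": None,
            "dmrs_by_id": {},
        }
    traits = dmr_trait_levels(matrix, dmrs_by_id)
    traits = traits[gm.samples]
    K = meqtl.ibs_kinship(gm.dosage)
    # top genotype PCs as fixed covariates for population structure
    G = gm.dosage.T.copy()
    mu = np.nanmean(G, axis=0)
    G[np.isnan(G)] = np.broadcast_to(mu, G.shape)[np.isnan(G)]
    Gc = G - G.mean(axis=0)
    if params.n_genotype_pcs > 0 and Gc.shape[1] >= params.n_genotype_pcs:
        _, _, Vt = np.linalg.svd(Gc, full_matrices=False)
        pcs = Gc @ Vt[: params.n_genotype_pcs].T
    else:
        pcs = None
    threshold = meqtl.bonferroni_threshold(gm.n_snps, params.alpha)
    significant = []
    for dmr_id, row in traits.iterrows():
        y = row.to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < 5:
            continue
        yt = meqtl.inverse_normal_transform(y[ok])
        sub_gm = popgen_scan.GenotypeMatrix(
            snps=gm.snps, dosage=gm.dosage[:, ok], samples=[s for s, o in zip(gm.samples, ok) if o]
        )
        Ksub = K[np.ix_(ok, ok)]
        cov = pcs[ok] if pcs is not None else None
        null = meqtl.lmm_null_fit(yt, Ksub, covariates=cov)
        assoc = meqtl.lmm_scan(yt, sub_gm, null, dmr_id, covariates=cov)
        hits = [a for a in assoc if a.p_value < threshold]
        if hits:
            clumped = meqtl.ld_clump(hits, gm, r2_max=params.r2_max, window=params.local_dist)
            keep = set(clumped.retained)
            significant.extend(a for a in hits if a.snp_id in keep)
    coords = {i: (d.chrom, d.start, d.end) for i, d in dmrs_by_id.items()}
    significant = meqtl.classify_local_distal(
        significant, coords, local_dist=params.local_dist
    )
    frac, pure = meqtl.pure_dmr_fraction(list(dmrs_by_id), significant)
    return {
        "n_traits": len(traits),
        "threshold": threshold,
        "significant": significant,
        "pure_fraction": frac,
        "pure_dmrs": pure,
        "kinship": K,
        "dmrs_by_id": dmrs_by_id,
    }


def stage_annotate(matrix, calls: dict, sweeps: dict, gm, annotation, populations, params: RunParams):
    """Overlap grouping, co-evolution, composition, diversity attribution."""
    members: dict[str, list] = {}
    for acc, pop in populations.items():
        members.setdefault(pop, []).append(acc)
    out = {}
    genome_bp = sum(annotation.chrom_lengths.values())
    for comp in COMPARISONS:
        groups = dmr_annotator.classify_context_overlap(
            calls[comp]["CG"], calls[comp]["CHG"]
        )
        coevo = dmr_annotator.coevolution_correlation(groups, matrix, members)
        dmr_regions = [
            (d.chrom, d.start, d.end)
            for ctx in DMR_CONTEXTS
            for d in calls[comp][ctx]
        ]
        dsr_regions = [(r.chrom, r.start, r.end) for r in sweeps[comp]["regions"]]
        comp_out = {
            "overlap_groups": groups,
            "coevolution": coevo,
            "n_o_cg": len(groups.o_cg),
            "n_o_chg": len(groups.o_chg),
            "n_u_cg": len(groups.u_cg),
            "n_u_chg": len(groups.u_chg),
        }
        if dmr_regions:
            comp_out["dmr_composition"] = dmr_annotator.genomic_composition(
                dmr_regions, annotation, flank=params.flank
            )
        if dsr_regions:
            comp_out["dsr_composition"] = dmr_annotator.genomic_composition(
                dsr_regions, annotation, flank=params.flank
            )
        # diversity attribution: DMR vs DSR vs the rest of the genome (NSR)
        occupied = popgen_scan.merge_intervals(
            [(c, s, e) for c, s, e in dmr_regions + dsr_regions]
        )
        nsr = []
        by_chrom: dict[str, list] = {c: [] for c in annotation.chrom_lengths}
        for c, s, e, _ in occupied:
            by_chrom[c].append((s, e))
        for c, length in annotation.chrom_lengths.items():
            cur = 0
            for s, e in sorted(by_chrom[c]):
                if s > cur:
                    nsr.append((c, cur, s))
                cur = max(cur, e)
            if cur < length:
                nsr.append((c, cur, length))
        all_acc = [a for mem in members.values() for a in mem]
        for label, regs in [("dmr", dmr_regions), ("dsr", dsr_regions), ("nsr", nsr)]:
            if regs:
                pi = popgen_scan.region_diversity(gm, regs, all_acc)
                lens = (pi["end"] - pi["start"]).to_numpy()
                # length-weighted mean: total pairwise differences per bp
                comp_out[f"pi_{label}"] = float(
                    (pi["pi"].to_numpy() * lens).sum() / lens.sum()
                )
        out[comp] = comp_out
    dom = [
        (d.chrom, d.start, d.end)
        for ctx in DMR_CONTEXTS
        for d in calls["domestication"][ctx]
    ]
    imp = [
        (d.chrom, d.start, d.end)
        for ctx in DMR_CONTEXTS
        for d in calls["improvement"][ctx]
    ]
    out["shared_dmrs"] = dmr_annotator.shared_regions(dom, imp)
    out["shared_dsrs"] = dmr_annotator.shared_regions(
        [(r.chrom, r.start, r.end) for r in sweeps["domestication"]["regions"]],
        [(r.chrom, r.start, r.end) for r in sweeps["improvement"]["regions"]],
    )
    out["genome_bp"] = genome_bp
    return out


def stage_correlate(matrix, calls, expression, annotation, params: RunParams):
    """Expression quartile profiles and DMR-gene correlation."""
    groups = expr_corr.expression_quartile_groups(expression)
    profiles = {
        ctx: expr_corr.groupwise_metaprofile(
            matrix, annotation.genes, groups, ctx, flank=params.flank
        )
        for ctx in DMR_CONTEXTS
    }
    dmrs_by_id = {}
    for comp, by_ctx in calls.items():
        for ctx, dmrs in by_ctx.items():
            for k, d in enumerate(dmrs):
                dmrs_by_id[f"{comp[:3]}_{ctx}_{k:04d}"] = d
    correlations = []
    if dmrs_by_id:
        regions = [(d.chrom, d.start, d.end) for d in dmrs_by_id.values()]
        pairs = dmr_annotator.genes_near_regions(
            regions,
            annotation.genes,
            flank=params.flank,
            region_ids=list(dmrs_by_id),
        )
        levels = dmr_trait_levels(matrix, dmrs_by_id)
        correlations = expr_corr.dmr_expression_correlation(
            levels, expression, pairs
        )
    return {
        "groups": groups,
        "profiles": profiles,
        "correlations": correlations,
        "summary": expr_corr.correlation_summary(correlations),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    return obj


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages in dependency order and write the run report."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params

    logger.info("stage simulate")
    sim_cfg = SimulationConfig(**{**config.simulate, "seed": config.seed})
    dataset = simulate_dataset(sim_cfg)
    write_dataset(dataset, outdir / "dataset")

    logger.info("stage methylome")
    populations = dict(
        zip(dataset.sample_sheet["accession"], dataset.sample_sheet["population"])
    )
    pooled = {
        acc: methylome_core.filter_coverage(
            dataset.accession_records(acc), params.min_reads
        )
        for acc in dataset.accessions
    }
    matrix = methylome_core.build_methylation_matrix(
        pooled,
        populations=populations,
        min_fraction_present=params.min_fraction_present,
        min_reads=params.min_reads,
    )
    methylome_summary = methylome_core.population_level_summary(
        matrix, dataset.sample_sheet
    )

    logger.info("stage dmr")
    calls = stage_dmr(matrix, populations, params)
    dmr_report = {}
    for comp, by_ctx in calls.items():
        dmr_report[comp] = {}
        for ctx, dmrs in by_ctx.items():
            s = dmr_caller.summarize_dmrs(dmrs)
            dmr_report[comp][ctx] = {
                "n": len(dmrs),
                "n_hyper": s.n_hyper,
                "n_hypo": s.n_hypo,
                "total_len_hyper": s.total_len_hyper,
                "total_len_hypo": s.total_len_hypo,
            }
            dmr_caller.dmrs_to_frame(dmrs).to_csv(
                outdir / f"dmrs_{comp}_{ctx}.bed", sep="\t", index=False, header=False
            )
        dmr_report[comp]["total"] = sum(
            dmr_report[comp][ctx]["n"] for ctx in DMR_CONTEXTS
        )
    dmr_report["grand_total"] = sum(dmr_report[c]["total"] for c in COMPARISONS)

    logger.info("stage sweep")
    sweeps = stage_sweep(dataset.genotypes, populations, dataset.chrom_lengths, params)
    sweep_report = {
        comp: {
            "thresholds": sweeps[comp]["thresholds"],
            "n_regions": len(sweeps[comp]["regions"]),
            "total_bp": sum(r.end - r.start for r in sweeps[comp]["regions"]),
        }
        for comp in COMPARISONS
    }

    logger.info("stage annotate")
    annotate = stage_annotate(
        matrix, calls, sweeps, dataset.genotypes, dataset.annotation, populations, params
    )
    annotate_report = {
        comp: {
            k: v
            for k, v in annotate[comp].items()
            if k not in ("overlap_groups",)
        }
        for comp in COMPARISONS
    }
    annotate_report["shared_dmrs"] = annotate["shared_dmrs"]
    annotate_report["shared_dsrs"] = annotate["shared_dsrs"]

    logger.info("stage meqtl")
    mq = stage_meqtl(matrix, dataset.genotypes, calls, params)
    sig = mq["significant"]
    meqtl_report = {
        "n_traits": mq["n_traits"],
        "n_snps": dataset.genotypes.n_snps,
        "threshold": mq["threshold"],
        "n_significant": len(sig),
        "n_local": sum(1 for a in sig if a.locality == "local"),
        "n_distal": sum(1 for a in sig if a.locality == "distal"),
        "pure_fraction": mq["pure_fraction"],
    }

    logger.info("stage correlate")
    corr = stage_correlate(matrix, calls, dataset.expression, dataset.annotation, params)
    corr_report = {"summary": corr["summary"]}
    truth_cg = {c["gene_id"]: c["dmr_id"] for c in dataset.truth.coupled_genes}
    coupled_r = [
        c.pcc
        for c in corr["correlations"]
        if c.gene_id in truth_cg and not np.isnan(c.pcc)
    ]
    corr_report["coupled_gene_mean_r"] = (
        float(np.mean(coupled_r)) if coupled_r else None
    )

    report = {
        "seed": config.seed,
        "params": params.model_dump(),
        "counts": {
            "accessions": len(dataset.accessions),
            "sites_in_matrix": matrix.n_sites,
            "snps": dataset.genotypes.n_snps,
        },
        "methylome": methylome_summary,
        "dmr": dmr_report,
        "sweep": sweep_report,
        "annotate": annotate_report,
        "meqtl": meqtl_report,
        "correlation": corr_report,
        "wall_clock_s": time.time() - t0,
    }
    ok, violations = validate_report(report)
    report["valid"] = ok
    report["violations"] = violations
    (outdir / "run_report.json").write_text(
        json.dumps(_jsonable(report), indent=2)
    )
    if not ok:
        logger.warning("report failed validation: %s", violations)
    return report


def validate_report(report: dict) -> tuple[bool, list[str]]:
    """Check the report's additive identities and threshold echoes."""
    violations = []
    dmr = report.get("dmr", {})
    for comp in COMPARISONS:
        if comp not in dmr:
            violations.append(f"missing dmr section for {comp}")
            continue
        total = dmr[comp].get("total")
        parts = sum(dmr[comp].get(ctx, {}).get("n", 0) for ctx in DMR_CONTEXTS)
        if total != parts:
            violations.append(
                f"{comp}: DMR total {total} != CG + CHG = {parts}"
            )
        for ctx in DMR_CONTEXTS:
            sec = dmr[comp].get(ctx, {})
            if sec and sec["n"] != sec["n_hyper"] + sec["n_hypo"]:
                violations.append(f"{comp}/{ctx}: n != hyper + hypo")
    if "grand_total" in dmr:
        s = sum(dmr[c]["total"] for c in COMPARISONS if c in dmr)
        if dmr["grand_total"] != s:
            violations.append("grand_total != sum of comparison totals")
    mq = report.get("meqtl", {})
    if mq:
        if mq["n_local"] + mq["n_distal"] != mq["n_significant"]:
            violations.append("local + distal != significant associations")
        if "threshold" not in mq:
            violations.append("meQTL threshold not echoed")
    for comp, sec in report.get("annotate", {}).items():
        if not isinstance(sec, dict):
            continue
        for key in ("dmr_composition", "dsr_composition"):
            if key in sec and sec[key]:
                s = sum(sec[key].values())
                if abs(s - 1.0) > 1e-6:
                    violations.append(f"{comp}/{key}: fractions sum to {s}")
    for comp, sec in report.get("sweep", {}).items():
        if "thresholds" not in sec:
            violations.append(f"{comp}: sweep thresholds not echoed")
    return (not violations), violations
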