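"""Synthetic multi-population WGBS / SNP / expression panels.

Emulates the statistical structure of a three-stage domestication panel
(wild -> landrace -> improved accessions, two biological replicates
each): a small global methylation increase per stage, planted DMRs with
known effect sizes and directions, Balding-Nichols population structure
with planted selective sweeps, SNP-driven (meQTL) methylation at chosen
DMRs, and genes whose expression is coupled to promoter methylation at a
target Pearson correlation.  A machine-readable truth table accompanies
every dataset so downstream callers can be scored against planted
ground truth.

Read counts are binomial draws at Poisson coverage around accession
latent levels, which are Beta-jittered around the population mean
(concentration ``beta_concentration``), giving realistic
between-accession variance.  CHH sites are simulated at low baseline but
carry no planted DMRs.  Raw reads, bisulfite-conversion error and
alignment artifacts are not modelled.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dmr_annotator import AnnotationSet
from .popgen_scan import GenotypeMatrix

STAGES = {"wild": 0, "landrace": 1, "improved": 2}
COMPARISONS = {
    "domestication": ("wild", "landrace"),
    "improvement": ("landrace", "improved"),
}
DMR_SITE_SPACING = 40  # bp between planted cytosines, well under the 300-bp gap rule
MEQTL_FREQ_LO = 0.15  # planted meQTL allele frequency in the ancestral stage
MEQTL_FREQ_HI = 0.85  # and in the derived stages (differentiated, DMR-causing)
MEQTL_BASE_LEVEL = 0.25  # region level = base + effect * dosage, no clipping
SWEEP_WIDTH = 30_000
GENE_LENGTH = 3_000
EXON_OFFSETS = [(0, 600), (1_200, 1_800), (2_400, 3_000)]


def _default_baseline():
    return {"CG": 0.60, "CHG": 0.35, "CHH": 0.08}


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic panel.

    Defaults give a 2 x 2-Mb genome with 12 accessions per population --
    small enough for routine test runs, large enough for 10-kb/1-kb
    sliding windows and gap-rule DMR blocks to behave as on real data.
    """

    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_per_pop: int = 12
    replicates_per_accession: int = 2
    n_sites_per_context: int = 6_000  # background sites per chromosome per context
    mean_coverage: float = 20.0
    baseline_level: dict = field(default_factory=_default_baseline)
    stage_shift: float = 0.03
    n_planted_dmrs: int = 20  # per comparison (domestication and improvement)
    dmr_effect: float = 0.4
    dmr_effect_spread: float = 0.2  # planted |effect| ladder half-width
    dmr_n_sites: int = 12
    coupling_fraction: float = 0.5  # CG DMRs that get a co-located CHG DMR
    n_snps: int = 40_000  # ~10 SNPs/kb, the density of a deep resequencing panel
    fst_target: float = 0.10
    n_sweeps: int = 4  # per comparison
    sweep_diversity_reduction: float = 0.1
    n_meqtl_dmrs: int = 2
    meqtl_effect: float = 0.3
    n_coupled_genes: int = 10
    expr_coupling_rho: float = -0.7
    beta_concentration: float = 50.0
    n_genes: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_pop < 4:
            raise ValueError("n_per_pop must be >= 4")
        if self.dmr_n_sites < 8:
            raise ValueError("dmr_n_sites must be >= 8")
        for ctx, v in self.baseline_level.items():
            if not 0 <= v <= 1:
                raise ValueError(f"baseline_level[{ctx}] outside [0,1]")
        for name in ("dmr_effect", "coupling_fraction", "meqtl_effect"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0,1]")
        if self.dmr_effect_spread < 0:
            raise ValueError("dmr_effect_spread must be >= 0")
        if self.dmr_effect > 0 and self.dmr_effect + self.dmr_effect_spread > 0.65:
            raise ValueError(
                "dmr_effect + dmr_effect_spread must be <= 0.65 so planted "
                "levels stay inside [0,1] around the 0.3/0.7 region baselines"
            )
        if not 0 <= self.fst_target < 1:
            raise ValueError("fst_target outside [0,1)")
        if not 0 < self.sweep_diversity_reduction <= 1:
            raise ValueError("sweep_diversity_reduction outside (0,1]")
        if abs(self.expr_coupling_rho) >= 1:
            raise ValueError("|expr_coupling_rho| must be < 1")
        if self.n_meqtl_dmrs > self.n_planted_dmrs:
            raise ValueError("n_meqtl_dmrs cannot exceed n_planted_dmrs")
        # every planted region needs a disjoint slot on the genome
        n_slots = 2 * self.n_planted_dmrs + 2 * self.n_sweeps
        genome = self.n_chroms * self.chrom_length
        dmr_width = (self.dmr_n_sites - 1) * DMR_SITE_SPACING + DMR_SITE_SPACING
        min_slot = max(SWEEP_WIDTH, dmr_width) + 2 * GENE_LENGTH + 4_000
        if n_slots and genome / n_slots < min_slot:
            raise ValueError(
                f"planted regions do not fit disjointly: {n_slots} slots of "
                f">= {min_slot} bp needed on a {genome} bp genome"
            )


@dataclass
class PlantedTruth:
    """Ground truth for every planted signal, JSON-serialisable."""

    dmr_regions: list[dict] = field(default_factory=list)
    sweep_regions: list[dict] = field(default_factory=list)
    meqtl_pairs: list[dict] = field(default_factory=list)
    coupled_genes: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def dmr_by_id(self) -> dict[str, dict]:
        return {d["dmr_id"]: d for d in self.dmr_regions}


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    chrom_lengths: dict[str, int]
    sample_sheet: pd.DataFrame  # accession, population, replicate
    sites: pd.DataFrame  # chrom, pos (1-based), strand, context, trinucleotide
    meth: np.ndarray  # (n_sites, n_accessions, n_reps) methylated read counts
    total: np.ndarray  # matching total read counts
    accessions: list[str]
    genotypes: GenotypeMatrix
    expression: pd.DataFrame  # genes x accessions, FPKM-like
    annotation: AnnotationSet
    truth: PlantedTruth

    def replicate_records(self, accession: str, rep: int) -> pd.DataFrame:
        """Cytosine-report records (7-column layout) for one replicate."""
        i = self.accessions.index(accession)
        df = self.sites.copy()
        df["n_meth"] = self.meth[:, i, rep]
        df["n_unmeth"] = self.total[:, i, rep] - self.meth[:, i, rep]
        return df[
            ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide"]
        ]

    def accession_records(self, accession: str) -> pd.DataFrame:
        """Replicate-pooled records for one accession (counts summed)."""
        i = self.accessions.index(accession)
        df = self.sites[["chrom", "pos", "strand", "context"]].copy()
        df["n_meth"] = self.meth[:, i, :].sum(axis=1)
        df["n_total"] = self.total[:, i, :].sum(axis=1)
        return df


def _place_slots(config: SimulationConfig, rng: np.random.Generator):
    """Reserve one disjoint genomic slot per planted region, shuffled."""
    n_slots = 2 * config.n_planted_dmrs + 2 * config.n_sweeps
    if n_slots == 0:
        return []
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    per_chrom = int(np.ceil(n_slots / config.n_chroms))
    slots = []
    for chrom in chroms:
        width = config.chrom_length // (per_chrom + 1)
        for k in range(per_chrom):
            center = (k + 1) * width
            slots.append((chrom, center))
    slots = [slots[i] for i in rng.permutation(len(slots))[:n_slots]]
    return slots


TRINUC = {"CG": "CGG", "CHG": "CAG", "CHH": "CAT"}


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full panel (genotypes, methylomes, expression, truth).

    Fixing ``config.seed`` fixes every output byte-for-byte.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_lengths = {c: config.chrom_length for c in chroms}

    # ---- panel ----------------------------------------------------------
    prefixes = {"wild": "W", "landrace": "L", "improved": "I"}
    accessions, pops = [], {}
    for pop in STAGES:
        for k in range(config.n_per_pop):
            name = f"{prefixes[pop]}{k + 1:02d}"
            accessions.append(name)
            pops[name] = pop
    stage = np.array([STAGES[pops[a]] for a in accessions])
    n_acc = len(accessions)
    sheet_rows = [
        {"accession": a, "population": pops[a], "replicate": f"{a}_rep{r + 1}"}
        for a in accessions
        for r in range(config.replicates_per_accession)
    ]
    sample_sheet = pd.DataFrame(sheet_rows)

    # ---- planted-region layout -----------------------------------------
    slots = _place_slots(config, rng)
    truth = PlantedTruth()
    dmr_width = (config.dmr_n_sites - 1) * DMR_SITE_SPACING + DMR_SITE_SPACING
    slot_iter = iter(slots)
    planted_dmrs = []  # dicts with placement + effect bookkeeping
    plant_effects = config.dmr_effect > 0
    plant_meqtl = config.meqtl_effect > 0 and config.n_meqtl_dmrs > 0
    n_pairs = max(1, (config.n_planted_dmrs + 1) // 2)
    for comp in COMPARISONS:
        for k in range(config.n_planted_dmrs):
            chrom, center = next(slot_iter)
            start = center - dmr_width // 2
            end = start + dmr_width
            direction = "hyper" if k % 2 == 0 else "hypo"
            # symmetric |effect| ladder around dmr_effect, shared by the
            # hyper/hypo member of each pair
            j = k // 2
            frac = j / (n_pairs - 1) if n_pairs > 1 else 0.5
            magnitude = config.dmr_effect + config.dmr_effect_spread * (2 * frac - 1)
            # SNP-driven DMRs: methylation set by a frequency-differentiated
            # local SNP, so the region is both a DMR and a true meQTL target
            is_meqtl = (
                plant_meqtl
                and comp == "domestication"
                and k >= config.n_planted_dmrs - config.n_meqtl_dmrs
            )
            coupled = (
                plant_effects
                and not is_meqtl
                and (k < config.coupling_fraction * config.n_planted_dmrs)
            )
            if is_meqtl:
                direction = "hyper"
                magnitude = config.meqtl_effect * 2 * (MEQTL_FREQ_HI - MEQTL_FREQ_LO)
            rec = {
                "dmr_id": f"{comp[:3]}_CG_{k:03d}",
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "context": "CG",
                "comparison": comp,
                "direction": direction,
                "effect": magnitude if direction == "hyper" else -magnitude,
                "coupled_chg": bool(coupled),
                "is_meqtl": bool(is_meqtl),
            }
            planted_dmrs.append(rec)
            if plant_effects or is_meqtl:
                public = {
                    k_: v
                    for k_, v in rec.items()
                    if k_ not in ("coupled_chg", "is_meqtl")
                }
                truth.dmr_regions.append(public)
                if coupled:
                    truth.dmr_regions.append(
                        {
                            **public,
                            "dmr_id": f"{comp[:3]}_CHG_{k:03d}",
                            "context": "CHG",
                        }
                    )
    sweep_regions = []
    for comp in COMPARISONS:
        for k in range(config.n_sweeps):
            chrom, center = next(slot_iter)
            start = max(0, center - SWEEP_WIDTH // 2)
            end = min(config.chrom_length, start + SWEEP_WIDTH)
            rec = {
                "sweep_id": f"{comp[:3]}_sweep_{k:03d}",
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "comparison": comp,
            }
            sweep_regions.append(rec)
            truth.sweep_regions.append(rec)

    # ---- genotypes ------------------------------------------------------
    positions = {}
    per_chrom_snps = config.n_snps // config.n_chroms
    snp_rows, snp_freqs = [], []
    for chrom in chroms:
        pos = np.sort(
            rng.choice(config.chrom_length - 1, size=per_chrom_snps, replace=False)
        ) + 1  # 1-based
        positions[chrom] = pos
        for p in pos:
            snp_rows.append((chrom, int(p)))
    F = config.fst_target
    pop_freqs = np.empty((len(snp_rows), 3))
    p_anc = rng.uniform(0.05, 0.95, size=len(snp_rows))
    for s in range(3):
        if F <= 0:
            pop_freqs[:, s] = p_anc
        else:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            pop_freqs[:, s] = rng.beta(a, b)
    # sweeps: push derived-stage frequencies toward fixation so that
    # expected heterozygosity drops by sweep_diversity_reduction
    r = config.sweep_diversity_reduction
    for rec in sweep_regions:
        derived_stages = [1, 2] if rec["comparison"] == "domestication" else [2]
        for i, (chrom, p1) in enumerate(snp_rows):
            if chrom != rec["chrom"] or not (rec["start"] <= p1 - 1 < rec["end"]):
                continue
            p = p_anc[i]
            disc = max(0.0, 1 - 4 * r * p * (1 - p))
            q_low = (1 - np.sqrt(disc)) / 2
            q = q_low if p < 0.5 else 1 - q_low
            for s in derived_stages:
                pop_freqs[i, s] = q
    # planted meQTL SNPs: local (10 kb upstream) and frequency-differentiated
    # between stages, so the genotype both creates the DMR and tags it
    meqtl_snps = []
    for d in planted_dmrs:
        if not d["is_meqtl"]:
            continue
        pos1 = max(1, d["start"] - 10_000)
        meqtl_snps.append(
            {"chrom": d["chrom"], "pos": pos1, "dmr_id": d["dmr_id"], "idx": None}
        )
        snp_rows.append((d["chrom"], pos1))
        pop_freqs = np.vstack(
            [pop_freqs, np.array([[MEQTL_FREQ_LO, MEQTL_FREQ_HI, MEQTL_FREQ_HI]])]
        )
    dosage = np.empty((len(snp_rows), n_acc))
    for i in range(len(snp_rows)):
        dosage[i] = rng.binomial(2, pop_freqs[i, stage])
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos"])
    snps["ref"] = "A"
    snps["alt"] = "G"
    snps["id"] = [f"snp_{c}_{p}" for c, p in zip(snps["chrom"], snps["pos"])]
    order = np.lexsort((snps["pos"].to_numpy(), snps["chrom"].to_numpy()))
    snps = snps.iloc[order].reset_index(drop=True)
    dosage = dosage[order]
    snps = snps.drop_duplicates(subset=["chrom", "pos"], keep="first")
    dosage = dosage[snps.index.to_numpy()]
    snps = snps.reset_index(drop=True)
    genotypes = GenotypeMatrix(snps=snps, dosage=dosage, samples=list(accessions))
    snp_index = {(c, p): i for i, (c, p) in enumerate(zip(snps["chrom"], snps["pos"]))}
    for m in meqtl_snps:
        m["idx"] = snp_index[(m["chrom"], m["pos"])]
        m["snp_id"] = snps["id"].iloc[m["idx"]]

    # ---- cytosine sites -------------------------------------------------
    site_frames = []
    for chrom in chroms:
        for ctx in ("CG", "CHG", "CHH"):
            pos = np.sort(
                rng.choice(config.chrom_length - 1, size=config.n_sites_per_context, replace=False)
            ) + 1
            strand = rng.choice(["+", "-"], size=len(pos))
            site_frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": pos, "strand": strand, "context": ctx}
                )
            )
    # planted DMR sites: evenly spaced within the region (and CHG twin)
    for d in planted_dmrs:
        if not (plant_effects or d["is_meqtl"]):
            continue
        base = d["start"] + DMR_SITE_SPACING // 2
        pos = base + DMR_SITE_SPACING * np.arange(config.dmr_n_sites) + 1
        site_frames.append(
            pd.DataFrame({"chrom": d["chrom"], "pos": pos, "strand": "+", "context": "CG"})
        )
        if d["coupled_chg"]:
            site_frames.append(
                pd.DataFrame(
                    {"chrom": d["chrom"], "pos": pos + 13, "strand": "+", "context": "CHG"}
                )
            )
    sites = pd.concat(site_frames, ignore_index=True)
    sites = sites.drop_duplicates(subset=["chrom", "pos"], keep="last")
    sites = sites.sort_values(["chrom", "pos"]).reset_index(drop=True)
    sites["trinucleotide"] = sites["context"].map(TRINUC)
    n_sites = len(sites)

    # ---- latent methylation levels -------------------------------------
    base = sites["context"].map(config.baseline_level).to_numpy(dtype=float)
    mean_level = base[:, None] + config.stage_shift * stage[None, :]
    pos0 = sites["pos"].to_numpy() - 1
    site_chrom = sites["chrom"].to_numpy()
    site_ctx = sites["context"].to_numpy()
    planted_by_id = {d["dmr_id"]: d for d in planted_dmrs}
    for d in planted_dmrs:
        if d["is_meqtl"] or not plant_effects:
            continue
        contexts = ["CG"] + (["CHG"] if d["coupled_chg"] else [])
        inside = (
            (site_chrom == d["chrom"])
            & (pos0 >= d["start"])
            & (pos0 < d["end"])
            & np.isin(site_ctx, contexts)
        )
        if not inside.any():
            continue
        # symmetric planting: hyper starts low and gains, hypo starts high and loses
        region_base = 0.3 if d["direction"] == "hyper" else 0.7
        affected = stage >= 1 if d["comparison"] == "domestication" else stage >= 2
        mean_level[inside] = (
            region_base
            + config.stage_shift * stage[None, :]
            + d["effect"] * affected[None, :]
        )
    for m in meqtl_snps:
        d = planted_by_id[m["dmr_id"]]
        inside = (
            (site_chrom == d["chrom"])
            & (pos0 >= d["start"])
            & (pos0 < d["end"])
            & (site_ctx == "CG")
        )
        # genotype-determined level: the allele-frequency shift between
        # stages is what makes this region a DMR
        mean_level[inside] = (
            MEQTL_BASE_LEVEL
            + config.stage_shift * stage[None, :]
            + config.meqtl_effect * genotypes.dosage[m["idx"]][None, :]
        )
        truth.meqtl_pairs.append(
            {
                "snp_id": m["snp_id"],
                "dmr_id": m["dmr_id"],
                "effect": config.meqtl_effect,
            }
        )
    mean_level = np.clip(mean_level, 1e-3, 1 - 1e-3)
    c = config.beta_concentration
    latent = rng.beta(mean_level * c, (1 - mean_level) * c)

    # ---- read counts ----------------------------------------------------
    n_reps = config.replicates_per_accession
    total = rng.poisson(config.mean_coverage, size=(n_sites, n_acc, n_reps))
    meth = rng.binomial(total, latent[:, :, None])

    # ---- annotation -----------------------------------------------------
    genes_rows, exon_rows = [], []
    per_chrom_genes = config.n_genes // config.n_chroms
    reserved = [
        (d["chrom"], d["start"] - 2 * GENE_LENGTH, d["end"] + 2 * GENE_LENGTH)
        for d in planted_dmrs
    ]

    def clashes(chrom, s, e):
        return any(c == chrom and s < re and rs < e for c, rs, re in reserved)

    gid = 0
    for chrom in chroms:
        pitch = config.chrom_length // (per_chrom_genes + 1)
        for k in range(per_chrom_genes):
            start = (k + 1) * pitch
            end = start + GENE_LENGTH
            if end > config.chrom_length or clashes(chrom, start, end):
                continue
            gene_id = f"gene_{gid:04d}"
            gid += 1
            strand = "+" if k % 2 == 0 else "-"
            genes_rows.append((gene_id, chrom, start, end, strand))
            for es, ee in EXON_OFFSETS:
                exon_rows.append((gene_id, chrom, start + es, start + ee))
    coupled_gene_ids = []
    if config.n_coupled_genes > 0 and plant_effects:
        cg_dmrs = [d for d in planted_dmrs]
        for j in range(min(config.n_coupled_genes, len(cg_dmrs))):
            d = cg_dmrs[j]
            gene_id = f"coupled_{j:03d}"
            if d["end"] + 500 + GENE_LENGTH <= config.chrom_length:
                start, end, strand = d["end"] + 500, d["end"] + 500 + GENE_LENGTH, "+"
            else:
                end, start, strand = d["start"] - 500, d["start"] - 500 - GENE_LENGTH, "-"
            genes_rows.append((gene_id, d["chrom"], start, end, strand))
            for es, ee in EXON_OFFSETS:
                exon_rows.append((gene_id, d["chrom"], start + es, start + ee))
            coupled_gene_ids.append((gene_id, d))
    genes_df = pd.DataFrame(
        genes_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    exons_df = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])
    te_rows = []
    for chrom in chroms:
        starts = np.sort(rng.choice(config.chrom_length - 3_000, size=80, replace=False))
        lengths = rng.integers(300, 3_000, size=80)
        classes = rng.choice(["Gypsy", "Copia", "LINE", "hAT"], size=80)
        for s, ln, cl in zip(starts, lengths, classes):
            te_rows.append((chrom, int(s), int(s + ln), cl))
    tes_df = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "te_class"])
    annotation = AnnotationSet(
        genes=genes_df, exons=exons_df, tes=tes_df, chrom_lengths=chrom_lengths
    )

    # ---- expression -----------------------------------------------------
    pooled_m = meth.sum(axis=2)
    pooled_t = total.sum(axis=2)
    expr = {}
    base_mu = rng.normal(3.0, 1.2, size=len(genes_df))
    for g, mu in zip(genes_df.itertuples(index=False), base_mu):
        y = mu + rng.normal(0, 0.5, size=n_acc)
        expr[g.gene_id] = np.maximum(np.exp2(y) - 1.0, 0.0)
    rho = config.expr_coupling_rho
    for gene_id, d in coupled_gene_ids:
        inside = (
            (site_chrom == d["chrom"])
            & (pos0 >= d["start"])
            & (pos0 < d["end"])
            & (site_ctx == "CG")
        )
        m = pooled_m[inside].sum(axis=0) / np.maximum(pooled_t[inside].sum(axis=0), 1)
        sd = m.std()
        x = (m - m.mean()) / sd if sd > 0 else np.zeros(n_acc)
        noise_sd = np.sqrt(1 / rho**2 - 1)
        y = 3.0 + np.sign(rho) * x + rng.normal(0, noise_sd, size=n_acc)
        expr[gene_id] = np.maximum(np.exp2(y) - 1.0, 0.0)
        truth.coupled_genes.append(
            {
                "gene_id": gene_id,
                "dmr_id": d["dmr_id"],
                "rho": rho,
                "location": "upstream",
            }
        )
    expression = pd.DataFrame(expr, index=accessions).T
    expression.index.name = "gene_id"

    return SyntheticDataset(
        config=config,
        chrom_lengths=chrom_lengths,
        sample_sheet=sample_sheet,
        sites=sites,
        meth=meth,
        total=total,
        accessions=accessions,
        genotypes=genotypes,
        expression=expression,
        annotation=annotation,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# writers


def _write_vcf(gm: GenotypeMatrix, chrom_lengths: dict, path: Path) -> None:
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i, row in enumerate(gm.snps.itertuples(index=False)):
            calls = [
                gt_map[int(d)] if not np.isnan(d) else "./."
                for d in gm.dosage[i]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def _write_gff3(genes: pd.DataFrame, exons: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        exon_groups = dict(tuple(exons.groupby("gene_id", sort=False)))
        for g in genes.itertuples(index=False):
            fh.write(
                f"{g.chrom}\tpopmeth\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for k, ex in enumerate(
                exon_groups.get(g.gene_id, pd.DataFrame()).itertuples(index=False)
            ):
                fh.write(
                    f"{ex.chrom}\tpopmeth\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{k + 1};Parent={g.gene_id}\n"
                )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write the dataset to disk; returns a manifest of files + checksums.

    Layout: per-replicate cytosine reports (Bismark cytosine-report
    dialect, 1-based positions), a VCF 4.2, GFF3 genes + BED6 TEs, an
    expression TSV, the sample sheet and the truth JSON.
    """
    if len(dataset.accessions) == 0:
        raise ValueError("empty panel: no accessions to write")
    outdir = Path(outdir)
    meth_dir = outdir / "methylomes"
    ann_dir = outdir / "annotation"
    meth_dir.mkdir(parents=True, exist_ok=True)
    ann_dir.mkdir(parents=True, exist_ok=True)
    files = []

    sheet = dataset.sample_sheet.copy()
    rep_files = []
    for row in sheet.itertuples(index=False):
        rep_no = int(row.replicate.rsplit("rep", 1)[1]) - 1
        rel = f"methylomes/{row.replicate}.CX_report.txt"
        rep_files.append(rel)
        recs = dataset.replicate_records(row.accession, rep_no)
        recs.to_csv(outdir / rel, sep="\t", header=False, index=False)
        files.append(rel)
    sheet["file"] = rep_files
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    files.append("samples.tsv")

    _write_vcf(dataset.genotypes, dataset.chrom_lengths, outdir / "genotypes.vcf")
    files.append("genotypes.vcf")
    _write_gff3(
        dataset.annotation.genes, dataset.annotation.exons, ann_dir / "genes.gff3"
    )
    files.append("annotation/genes.gff3")
    tes = dataset.annotation.tes
    bed = pd.DataFrame(
        {
            "chrom": tes["chrom"],
            "start": tes["start"],
            "end": tes["end"],
            "name": tes["te_class"],
            "score": 0,
            "strand": "+",
        }
    )
    bed.to_csv(ann_dir / "tes.bed", sep="\t", header=False, index=False)
    files.append("annotation/tes.bed")

    dataset.expression.to_csv(outdir / "expression.tsv", sep="\t")
    files.append("expression.tsv")
    (outdir / "truth.json").write_text(dataset.truth.to_json())
    files.append("truth.json")

    with open(outdir / "chrom_lengths.tsv", "w") as fh:
        for chrom, length in dataset.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    files.append("chrom_lengths.tsv")

    manifest = {}
    for rel in files:
        digest = hashlib.sha256((outdir / rel).read_bytes()).hexdigest()
        manifest[rel] = digest
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
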