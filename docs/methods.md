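# Methods

`popmeth` re-implements, as a tested pipeline, a comparative
population-methylome analysis across a domestication series: panels of
wild, landrace and improved accessions with whole-genome bisulfite
sequencing (WGBS), resequencing SNPs and expression data. This note
documents the models, the defaults and why they were chosen, what the
synthetic panels do and do not emulate, and the numerical corner cases.

## Methylome processing

A cytosine site's methylation level is `m/t` — methylated reads over
total reads — from Bismark-style cytosine reports (1-based positions;
everything internal is 0-based half-open). Two biological replicates per
accession are pooled by **summing counts**, not averaging levels: the
binomial observation model makes pooled counts the sufficient statistic,
and it weights a deeply covered replicate appropriately. Sites need
strictly more than `min_reads = 3` pooled reads to count as observed,
and enter the matrix only when observed in ≥ 70 % of the accessions of
*every* population (`min_fraction_present`, mirroring the SNP missing-rate
filter on the genotype side).

Region levels use the **weighted convention** Σm/Σt over in-region
sites. This differs from the unweighted mean of site levels (a worked
example in the tests: sites 1/4 and 9/16 give 10/20 = 0.5, not 0.406)
and is the convention used wherever a region becomes a trait.

CG sites are kept per strand; no dyad merging is applied by default
since the upstream convention the data follows is unknown in general.

Metaprofiles use 20 bins over the 2-kb upstream flank, 40 over the body
(fractional coordinates, so short features still bin), 20 downstream;
minus-strand features are reversed so bin 1 is always 5′-most. Sites are
averaged across accessions first, then within feature per bin, then
across features — so every feature contributes equally regardless of its
site density.

Population comparisons report a paired two-tailed t-test. Populations
have no natural pairing, so accessions are paired by the rank of their
genome-wide mean within population, truncated to the smaller n, with the
unpaired Welch test reported alongside; zero-variance paired differences
are degenerate and reported as p = 1 (all-zero) or p = 0 (constant
non-zero shift) with a warning.

## DMR calling

The caller is an equivalent-by-criteria implementation of a
metilene-style procedure. A region is a DMR iff it satisfies, between
the two populations and within one context (CG or CHG; CHH is excluded):

1. ≥ 8 cytosine sites,
2. every adjacent-site gap < 300 bp (strict),
3. |mean level difference| > 0.25 (strict),
4. Benjamini–Hochberg q < 0.01 across all tested segments of the
   comparison/context (Bonferroni selectable).

Candidates are maximal site runs under the gap rule, recursively split
by **mean-difference binary segmentation**: the breakpoint maximising
the separation of the two children's mean per-site differences is
accepted when both children keep ≥ 8 sites and the stronger child
improves on the parent's |mean difference| by more than ε = 0.02. The
ε threshold stops noise-chasing splits; its value is small relative to
the 0.25 effect filter so it cannot hide a passing region. Each
segment is tested by a Mann–Whitney U on accession-level segment means
(accessions, not replicates, are the experimental units), exact for
small tie-free samples, tie-corrected normal approximation otherwise.
The test-suite enforces an exhaustive-window oracle: no emitted region
may violate any filter when re-derived by brute force.

Direction is later-stage minus earlier-stage: `hyper` means the derived
population gained methylation.

## Sweep scanning

Per-site diversity is π = 2j(n−j)/(n(n−1)) for alt count j among n
called alleles — the unbiased pairwise-difference estimator, verified
against pair enumeration for all (j, n), n ≤ 20. Windows are 10 kb with
a 1-kb step; window π is Σ site-π divided by the window span, and window
F_ST is the Weir–Cockerham (1984) ratio of sums Σa/Σ(a+b+c) with
negative estimates retained (matching common VCF-toolchain semantics).
Sweep regions (DSRs) are windows exceeding *both* the empirical 90th
percentile of the ancestral/derived π ratio and of F_ST, merged when
overlapping or book-ended. The thresholds are data properties reported
in the run output, never constants. Windows with zero derived π are
excluded from the ratio ranking (logged) rather than treated as
infinite.

Region diversity in the run report is length-weighted (total pairwise
differences per bp over the region set); the unweighted mean over
sub-kb regions is noise-dominated at any realistic SNP density.

## meQTL mapping

Each called DMR's per-accession weighted level is a trait:
rank-based inverse-normal transformed (Blom offset c = 3/8, average
ranks on ties), then scanned under

  y = Xβ + u + ε, u ~ N(0, σ²_g K), ε ~ N(0, σ²_e I)

with K the identity-by-state kinship K_ij = mean(1 − |d_i − d_j|/2) and
X an intercept plus the top two genotype principal components. The
variance ratio δ = σ²_e/σ²_g is fitted once per trait by REML on the
eigendecomposition of K (coarse grid over log δ ∈ [−10, 10], Brent
refinement) and held fixed across SNPs — the EMMAX approximation, which
keeps the scan O(SNPs). Each SNP's Wald t-test is then weighted least
squares in the rotated basis with per-SNP residual variance, so with
K = I the test reduces *exactly* to simple regression (asserted to
1e−6 in the tests). Missing dosages are mean-imputed per SNP;
monomorphic SNPs are skipped.

The PC covariates matter: with kinship alone, a random trait's p-values
are mis-calibrated in either direction depending on how the trait
happens to align with the low-rank population structure; with two PCs
the genomic-control λ sits within a few percent of 1 across seeds.
Relatedly, "pure-noise traits give near-zero heritability" is only a
meaningful check on a *structured* kinship — for i.i.d. genotypes the
IBS matrix is ≈ aI + b11ᵀ and δ is unidentifiable.

Significance is Bonferroni at α = 0.01 over the number of SNPs tested.
Significant SNPs are greedily LD-clumped (accept best p, drop SNPs
within 1 Mb at r² ≥ 0.25 with anything accepted), then classified
**local** (same chromosome, ≤ 1 Mb from the nearest DMR edge; 0 inside)
or **distal**. DMRs with no surviving association are **pure DMRs**.

## Expression coupling

Genes are split into four near-equal expression groups (low / mid-low /
mid-high / high) on mean FPKM across accessions, sorted ascending with
stable ties and earlier chunks taking the extra gene; all-zero genes
land in "low". Group metaprofiles reuse the 20/40/20 binning. Per-pair
DMR–gene correlation is Pearson on log2(FPKM+1) (raw scale selectable;
Pearson is affine-invariant so the FPKM unit is immaterial) over ≥ 5
jointly observed accessions, with gene proximity defined as overlap of
the DMR with the gene body or either 2-kb flank, strand-aware.

## The synthetic panels

The generator emulates the statistical structure of a domestication
methylome panel — it is the fixture factory for every downstream test,
with a machine-readable truth table. Defaults (the modelled study
conditions at desk scale):

| parameter | default | rationale |
|---|---|---|
| genome | 2 chromosomes × 2 Mb | large enough for 10 kb/1 kb windows and 500-kb tiles, small enough for CI |
| accessions | 12 per population × 2 replicates | close to a typical ~40-accession, three-population panel |
| background sites | 6,000 per context per chromosome (3/kb) | gives both qualifying and gap-broken site runs under the 300-bp rule |
| coverage | Poisson(20) per site/replicate | typical WGBS depth |
| baselines | CG 0.60, CHG 0.35, CHH 0.08 | plant-like context hierarchy; CHH never carries planted effects |
| stage shift | +0.03 per stage | the global wild < landrace < improved increase |
| planted DMRs | 20 per comparison, 12 sites, 40-bp spacing | clear the ≥8-site and <300-bp rules with margin |
| planted \|effect\| | 0.4 ± 0.2 ladder | realistic effect-size spread; the hyper/hypo pair of a rung shares its magnitude, so effects stay symmetric and the mean \|Δ\| equals 0.4. Near-threshold rungs make hyper-dominance emerge from the stage shift rather than being planted |
| SNPs | 40,000 (~10/kb) | resequencing-panel density |
| F_ST target | 0.10 (Balding–Nichols) | moderate crop-panel differentiation |
| sweeps | 4 per comparison, 30 kb, heterozygosity ×0.1 | derived-stage frequencies pushed toward the nearer fixation boundary so that expected heterozygosity drops by the target factor |
| meQTL DMRs | 2 (5 % of planted DMRs) | region level = 0.25 + 0.3·dosage of a local SNP whose frequency shifts 0.15 → 0.85 across domestication — the genotype both creates the DMR and tags it, with no level clipping |
| coupled genes | 10 at ρ = −0.7 | gene placed so the DMR sits in its 2-kb promoter flank; expression built on the log2 scale from the realized region methylation with noise solving ρ = 1/√(1+σ²) |
| accession noise | Beta, concentration 50 | between-accession level jitter; makes rank tests non-degenerate. The concentration is a free parameter (no empirical estimate exists for it) |

Accession latent levels are Beta-jittered population means; replicates
are independent binomial draws at Poisson coverage from the same latent
level. Fixing the seed fixes every output byte (asserted on file
checksums).

**What the panels do not emulate** — and hence what green tests do not
establish about real data: raw reads, bisulfite-conversion error,
mapping bias (deep panels mitigate it with per-accession
pseudo-references), indels
and structural variants, LD decay within populations (SNPs are drawn
independently given the frequency model), spatially autocorrelated
methylation outside planted regions, TE-family-specific methylation,
and any genome-scale count (real panels call thousands of DMRs from
hundreds of gigabytes of sequence; desk-scale runs call tens).

## Numerical choices and degenerate inputs

- Empty matrices, windows, groups and region sets return empty/NaN
  results with warnings, never crashes; zero-length regions and empty
  panels are errors raised before any output is written.
- The site-level spectrum uses bins [0,0.1), …, [0.9,1.0] with the last
  bin closed.
- Kinship eigenvalues are floored at 1e−6 (with a warning if the matrix
  was materially non-PSD).
- PCA mean-imputes missing cells per site (complete-case deletion can
  empty the matrix at realistic missingness) and centers without
  scaling; a constant matrix yields all-zero coordinates.
- Quantile thresholds in the sweep scan use linear-interpolation
  empirical quantiles; selection is strict (>), matching the strict
  inequalities of the printed filters elsewhere.
- Ties in expression grouping are broken by input gene order (stable
  argsort), making the grouping deterministic.

## Problem sizes

Default test and demonstration runs use the 2 × 2 Mb panel
(36 accessions, ~36k cytosines, 40k SNPs): a full pipeline run takes
tens of seconds on one core, and the complete test-suite about a
minute. The reproduction script (`scripts/acceptance.py`) adds
multi-seed recall/recovery loops on a 2 × 1 Mb panel and a 10,000-SNP
null calibration, finishing in well under a minute.

## Known limitations

- The segmentation is not metilene's exact 2D-KS recursion; the two
  agree on what constitutes an acceptable DMR (the filter rules) but
  may draw different boundaries inside a block. Boundary trimming can
  split one planted region into two calls.
- At n ≈ 36–41 accessions, Bonferroni-corrected meQTL detection for a
  single tag SNP is marginal; most runs classify nearly all DMRs as
  pure. That matches what deep panels report (~97 % pure) but means the
  in-pipeline local/distal table is often empty at desk scale — the
  scan's power and calibration are therefore demonstrated in dedicated
  constructions in the test-suite.
- The paired t-test across populations is a documented interpretation
  of an under-specified procedure (populations have no natural
  pairing); the Welch test is always reported alongside.
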