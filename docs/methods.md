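# Methods

This note documents the statistical procedures implemented in `pathgwas`,
the modelling assumptions behind the synthetic-data generator, the
numerical conventions that make permutation results reproducible, and the
design choices made where the underlying methodology leaves room.

## Association model and QC

The primary statistic is the allelic 1-d.f. test: each SNP's genotypes are
collapsed to minor/major allele counts in cases and controls and tested
with a Pearson χ² on the 2×2 table, without Yates continuity correction —
the standard PLINK `--assoc` statistic.  Missing genotypes drop out of the
counts for that SNP only.  Both the allelic test and the Hardy–Weinberg
goodness-of-fit test use the χ² form rather than exact tests: at the
sample sizes this pipeline targets (hundreds of samples per group, common
variants after the MAF ≥ 0.01 filter) the χ² approximation is accurate,
and it keeps the permutation machinery a single matrix product.

QC runs in a fixed order — sample call rate, then per-SNP MAF, call rate
and control-group HWE (p ≥ 1e-4) — and each SNP is tallied at the first
filter it fails, so report counts are unambiguous.  MAF for the
minor/major assignment is computed on controls (cases are enriched for
risk alleles by construction); per-group MAFs are reported separately.
The assignment made at discovery load time is reused unchanged for a
replication cohort so direction comparisons are meaningful.

Genomic control uses the median estimator λ = median(χ²)/0.4549364 (the
1-d.f. χ² median).  LD is reported as the squared Pearson correlation of
composite genotypes over pairwise-complete samples — deterministic and
phase-free; it approximates haplotype r² and is adequate for the
"r² > 0.7" reporting convention, but it is not an EM haplotype estimator.

## Permutation engine

All permutation-based nulls relabel case/control status while preserving
group sizes.  One master seed drives a `SeedSequence`; each permutation
draws its labels from its own spawned substream, so the ensemble is
reproducible element-wise and independent of execution order.  Gen-Gen
and the SRT consume the *same* ensemble and the same per-permutation χ²
matrix (computed once as a label-by-genotype matrix product): both methods
are defined on identically permuted data, and sharing the scan halves the
dominant cost.  Aligator's null is SNP sampling, not permutation; it uses
a separate substream of the same master seed.

## Gen-Gen

Gene statistic: the largest allelic χ² among the gene's mapped SNPs.
Genes are ranked descending; ties break lexicographically by symbol — an
arbitrary but fixed rule, necessary because the ranking is recomputed for
every permutation and must be deterministic.  The enrichment score is the
*signed maximum* of the weighted KS running sum (not the maximum absolute
deviation), with the weight exponent (default w = 1) applied to both the
hit increments and their normaliser N_R, following the original GSEA
convention.  With all-zero member statistics (possible in tiny tests) the
hit increments fall back to uniform 1/N_H steps.

Per pathway, the empirical p is the fraction of permutations whose ES
reaches the observed ES — the s/N convention, so a pathway that beats
every permutation reports p = 0, printed as "< 1/N".  This deliberately
differs from the SRT's add-one rule: the two conventions are exactly what
produces the coexistence of "<0.001" and "0.001" entries at 1000
permutations in published Gen-Gen outputs alongside SRT values of 1/1001
and 2/1001.  NES standardises ES by the permutation mean and SD; when the
permutation SD is zero NES is reported missing (NaN).  The p is ES-based;
NES is reported alongside for cross-pathway comparison.

## Aligator

Gene significance: any mapped SNP with p < 0.01, strict inequality.
Replicate gene lists are grown by drawing SNPs uniformly *with
replacement* from all scanned SNPs and appending each drawn SNP's gene(s)
if new, until the list reaches exactly K genes; if a multi-gene SNP
overshoots, genes are added in position order and the list truncated at
K.  Exact-K lists keep per-pathway counts comparable across replicates.
Sampling SNPs rather than genes is the defining feature: a gene covered by
ten SNPs is ten times as likely to enter a replicate list, which cancels
the size bias in the observed significant-gene list (verified by the
gene-size-bias test).  The multiple-testing correction promotes one
replicate list to pseudo-observed data against a bootstrap resample of
the replicate pool, repeats (default 1000 rounds), and reports where the
observed count of significant gene sets falls in that null distribution —
a study-wide excess verdict, not per-pathway corrected p-values.  The
per-set significance threshold inside the correction is the global 0.05.

## SNP Ratio Test

Pathway statistic: the fraction of the pathway's distinct SNPs with
p < threshold.  The SNP significance threshold is not fixed by the
methodology this pipeline follows; the default is 0.05 (the SRT
convention) and it is exposed as `srt_snp_p`.  The empirical p is
(s+1)/(N+1) with ties counting toward s.  Because the ratio is discrete
(a count over at most a few hundred SNPs), ties with the observed ratio
are common under the null and the add-one p is *conservative*: its null
distribution is valid (P(p ≤ α) ≤ α + 1/(N+1)) but not exactly uniform on
the grid, and its null mean exceeds 0.5.  Calibration tests therefore
check validity for the SRT and exact grid-uniformity only for Gen-Gen,
whose continuous ES makes ties measure-zero.

## Consensus, validation, meta-analysis

Consensus: p < 0.05 in all three methods simultaneously; p ≤ 0.001 in any
method flags the "top" subset.  Ranks are competition ranks (ties share
the smallest rank) computed within each method's full pathway list.
Candidate SNPs are drawn from all consensus pathways by default, with a
`top_only` switch restricting to the flagged subset.  Validation requires
both cohorts significant at p < 0.05 (strict) *and* the same sign of
(case MAF − control MAF); direction is measured on the MAF difference
because that is the only effect direction the summary tables carry.

The meta-analysis is a Cochran–Mantel–Haenszel 1-d.f. test over the two
study-stratified 2×2 allele-count tables (statsmodels `StratifiedTable`,
no continuity correction), with pooled MAFs from summed counts.
Count-level pooling with study stratification matches tables that print
pooled MAFs next to a single pooled p.  A fixed-effect inverse-variance
alternative on log-OR would be a reasonable substitute but is not what
pooled-MAF reporting implies, so CMH is the default and only method.
Heterogeneity statistics (Q, I²) are out of scope.

## SNP→gene→pathway mapping

Windows are gene body ± `flank_bp` (default 20 kb), closed at both ends;
coordinates are 1-based fully closed (NCBI convention).  Strand is
ignored — the flank is symmetric.  A SNP may map to several overlapping
genes; pathway SNP counts are over distinct SNPs.  Pathway size filtering
(10–100 genes, inclusive bounds) is applied to raw GMT membership before
any SNP mapping, matching a workflow that filters pathway definitions
before chip-content restriction; `filter_on_raw_size=False` switches to
counting only annotated genes.  Gene symbols are uppercased on both sides
before matching; pathway genes without mapped SNPs are dropped from the
index (logged), and pathways with no mapped genes are flagged and skipped
by the enrichment engines.

## Synthetic data

The generator emulates the data structure the analysis assumes, not any
real genome: synthetic chromosomes, genes spaced so their ±20 kb windows
never overlap, 1–5 SNPs per gene placed inside the window, control MAFs
uniform on (0.05, 0.5], and *disjoint* pathways partitioning the gene
pool (so null pathways contain no planted signal and calibration tests
are clean).  Defaults mirror a discovery cohort of 969 cases and 957
controls; panel sizes are desk-scale by design and every size is a
parameter.

The disease model is allelic: an effect SNP with control frequency p and
per-allele odds ratio OR has case frequency p′ = OR·p/(1−p+OR·p), with
HWE within each group.  Because the analysis statistic is the allelic
test, the planted OR is directly recoverable — the generator's effect
parameter and the method's estimand coincide.  All SNPs of an effect gene
carry the gene's OR.  Missingness is applied uniformly at random (default
0.2%, typical post-QC).  SNPs are independent by default; an optional
within-gene LD mode makes each SNP copy a gene-level anchor genotype with
probability ρ (all SNPs of the gene then share the anchor's frequency),
used to exercise the permutation null under correlation.  What these
simulations do *not* model: realistic LD maps, population stratification,
genotyping batch effects, rare variants — so passing calibration and
recovery tests demonstrates correctness of the machinery under the stated
model, not robustness to those real-data complications.

Two-cohort simulation shares the panel, MAFs and effect assignments and
draws genotypes from independent streams; replication sample sizes scale
by a factor.

## Problem sizes used in the test suite

Calibration uses a null study of 2000 SNPs (400 genes × 5 SNPs), 500
cases / 500 controls, 50 pathways, 200 permutations.  Parameter recovery
uses 20 repetitions of a 1000/1000 study with one 30-gene pathway
containing 20 effect genes at OR 1.6, 200 permutations, Aligator at its
5000-replicate default.  Validation semantics use two 1000/1000 cohorts
with 250 effect SNPs at OR 1.5 among ~2100.  These sizes were chosen so
each property is measured with comfortable Monte-Carlo margins while the
whole suite stays interactive.

## Known limitations and recorded discrepancies

* The bundled published pathway table is internally inconsistent with its
  own consensus rule: BIOCARTA_NDKDYNAMIN_PATHWAY prints SRT p = 0.08991
  (= 90/1001, consistent with its printed SRT rank of 56), which is not
  below 0.05, yet the published consensus total is 18.  The strict rule
  implemented here therefore reproduces 17 of the 18 published rows.  The
  bundled tables follow the printed table wherever the surrounding text
  disagrees with it (several per-cohort p-values are swapped between
  cohorts in the text).
* p-values published only as bounds ("<0.001") are loaded as the largest
  float below the bound, preserving the comparisons the bound implies.
* The HWE and allelic tests are asymptotic; no exact-test option exists.
* No genotype imputation, ancestry correction, relatedness pruning or
  binary-PLINK/VCF ingestion; genotype I/O is plain-text TSV and
  .ped/.map.
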