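# Methods

## Scope and data model

`gbmkit` operates on the *processed* layer of a two-stage multiomics
study: per-cytosine methylation counts, gene-level expression tables
and histone-mark coverage tracks. Read-level processing (trimming,
alignment, deduplication, methylation extraction, differential
expression model fitting) is upstream of the package and out of
scope; differential-expression results are consumed as tables.

All interval arithmetic is 0-based half-open internally. GFF3
coordinates (1-based inclusive) and cytosine-report positions
(1-based) are converted at the I/O boundary. For multi-transcript
genes the exon chain E1..En follows the longest annotated transcript
(by summed exon length), while gene-level methylation uses the full
gene span; `gene_methylation_span: exons` switches to exonic
positions only. The full-span default reflects that both exons and
introns of gene bodies carry signal, and segment profiles (which show
exon > intron methylation) remain exon/intron-resolved regardless.
Methylation calls keep the two cytosines of a CpG dyad as separate
sites (the Bismark convention); `merge_cpg_dyads` pools them onto the
plus-strand position.

## Methylation calling and aggregation

A site is called at coverage ≥ `min_coverage` (default 5 reads); its
level is the percent of methylated reads. Feature means are
unweighted over covered CpGs and defined only at ≥ `min_cpgs`
(default 3). The consolidated gene set — genes defined in every
sample — is the universe for the four-way classification, transition
accounting and every overlap test, so set sizes are comparable across
stages. Conversion efficiency is 100 minus the pooled percent
methylated on the unmethylated Lambda spike-in; the methylated pUC19
spike-in checks the opposite failure mode. Spike-in records travel as
extra chromosomes named `Lambda`/`pUC19` and are split off before any
genomic statistic.

The genome-wide "percent of CpGs methylated" is reported under two
operational definitions — the mean per-CpG level, and the fraction of
CpGs at or above the 10% status threshold — because the summary
statistic is defined either way in the literature; neither is
privileged.

## Status thresholds

*Methylated* means mean gene-body level ≥ 10% (the "not methylated"
label is strictly below 10). *Expressed* means summary FPKM > 1
(FPKM exactly 1 is not expressed). The stage summary is the mean of
retained replicate FPKMs (median switchable). Replicate QC computes
Pearson correlations and a PCA on log2(FPKM+1); a replicate is
flagged when its *best* within-group correlation falls below the
floor (default 0.8). The flag is advisory: exclusion happens only
through `excluded_replicates` in the configuration. A median-based
flag was rejected because with three replicates and one outlier the
median (over two values) also drags the two good replicates under the
floor; the maximum isolates exactly the outlier.

## DMR calling

Input sites must be covered 5–100× in every replicate of both groups
(both bounds inclusive). Sites are chained into runs broken at
inter-CpG gaps > 300 bp, and each run is segmented by recursive
binary splitting of the per-CpG group-mean difference at the point
maximizing |mean(left) − mean(right)|, recursing while both children
keep ≥ 10 CpGs and the better child improves on the parent's absolute
mean difference. Because greedy splitting wobbles a few CpGs at true
region edges, each leaf is re-anchored on the nearby window (± 2 × 10
CpGs) maximizing the penalized area `Σ (sign·diff − min_diff)` — a
CpG joins only if it contributes beyond the minimum effect size, so
noise flanks (negative expected score) terminate the window while
true-region CpGs extend it. Overlapping refined windows resolve to
the stronger candidate. Leaves with |mean difference| ≥ 10 points
become candidates.

Candidates are tested with a two-sided Mann–Whitney U on the pooled
CpG × replicate level observations of the two groups. Raw p-values
are **permutation-calibrated**: candidates are re-derived under every
balanced relabeling of the samples (9 for a 3 vs 3 design, capped at
50), their raw MWU p-values pooled as the null distribution, and each
observed candidate scored by its rank in the pool. This step is
essential — segmentation *selects* extreme regions, and without
calibration essentially every noise candidate tests significant;
with it the empirical false-positive rate under null simulations is
at or below the nominal 0.05. BH correction runs across candidates;
survivors must satisfy all three region criteria (≥ 10 CpGs, ≥ 10
points, q < 0.05). `calibrate=False` exposes the uncalibrated path.
Constant (all-tied) data receives p = 1 by convention. BH ties
resolve identically regardless of genomic order since equal p-values
get equal adjusted values.

DMRs are *hypomethylated* when the second group (adult, by
convention) is lower. Feature annotation classifies each DMR as
exon-only, intron-only, exon+intron or intergenic; a DMR inside a
gene span but in no modelled feature (annotation gaps) counts as
intronic.

## Peak calling and consolidation

Sparse-enrichment calling is re-specified as: maximal runs of
positive adjacent signal become blocks scored by AUC; the top
⌈fraction · n⌉ blocks (default 2.5%) are retained per replicate, ties
at the cutoff broken by block maximum then genomic order. The
high-confidence set is the n-way intersection of replicate coverage
(≥ 1 bp), merged into maximal intervals; whole blocks are reported
(no summit reduction) since all downstream use is interval overlap.
Background-control normalization of the input tracks is out of scope;
tracks are assumed comparably normalized across replicates.

## Profiles

Metagene matrices use an upstream flank (3 kb), a body scaled to 5 kb
and a downstream flank (3 kb) at 50 bp bins. The per-base window is
oriented to transcription direction *first* and the body scaled
afterwards by the floor pre-image map (scaled base *j* takes the
value of base ⌊j·L/5000⌋); orienting first makes plus- and
minus-strand genes exactly mirror-symmetric, which is asserted as an
invariant. Track bins average per-base values; methylation bins
average the levels of covered CpGs and stay missing when a bin has
none. Anchored profiles use fixed ±0.5 kb windows around the
strand-aware TSS/TES; windows truncated by a chromosome edge hold
missing values. Set-mean profiles average over genes per bin,
ignoring missing cells, and report per-bin n and SE. Segment profiles
apply the ≥ 3-CpG rule per segment (U, E1–E5, I1–I4, D in
transcription order) per gene and weight genes equally in the
set-level mean. Neighboring genes are not masked from flanks by
default (`mask_flank_genes` reserved for that purpose).

## Overlap statistics and GO enrichment

All gene-set overlap tests are upper-tail hypergeometric
probabilities P(overlap ≥ observed) given the two set sizes and the
consolidated universe — the `phyper` convention, enrichment-only;
depletion is visible descriptively through the reported expected
overlap. GO enrichment is the classic one-sided Fisher's exact test
per term over direct annotations (optional ancestor propagation when
an ontology map is supplied), BH-corrected across tested terms; terms
without subset genes are untested. The gene ratio is 100 × (subset
genes with the term) / (universe genes with the term). Reporting
keeps the 40 most significant terms, ties broken by term id for
determinism.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes:

- **Genome**: non-overlapping genes with 1–8 exons (150–600 bp) and
  introns (100–500 bp) on random strands, ≥ 3 kb intergenic gaps;
  CpG sites with ~27 bp mean spacing in exons vs ~105 bp elsewhere.
- **Truth**: 25% of genes methylated with integer levels uniform in
  15–70% (unmethylated genes ≤ 7%); 36.5% expressed in embryos, with
  activation (17.5% of silent) and inactivation (9.3% of expressed)
  rates bringing adults to ~44%; methylation status maintained by
  ~95% of genes (16.8% of methylated genes lose, 0.7% of
  unmethylated gain); a true-level-0 dip within ±200 bp of the TSS of
  methylated/expressed genes; and a mild adult drift toward baseline
  (15% of the excess over 15 points) so higher-methylated genes tend
  to lose methylation between stages.
- **Planted DMRs**: 8 contiguous 15-CpG runs shifted −30 points in
  the adult, hosted in genes methylated ≥ 40% in both stages; host
  genes are exempt from the adult drift so the planted run is the
  only stage difference in its gene and the recorded truth interval
  is a well-defined target.
- **Methylome**: coverage Poisson(30); methylated counts
  beta-binomial around the site's true level with dispersion ρ = 0.1
  (configurable; ρ controls DMR power) after adding a conversion
  failure rate of 0.5% as false methylated calls — inside the
  conversion-efficiency range EM-seq protocols report. Lambda is 0%
  methylated, pUC19 100%. `exact=True` silences all noise (constant
  coverage 100, deterministic counts), making per-CpG levels equal
  the integer-percent truth exactly — the basis of the zero-noise
  recovery invariants.
- **Expression**: expressed genes draw log10 FPKM uniform in
  0.4–2.5, silent genes in −2..−0.2; methylated/expressed genes
  instead tie expression to methylation (log10 FPKM =
  0.5 + 0.01·level + N(0, 0.3), truncated above FPKM ≈ 1.1), giving
  the weak positive association the regression recovers. Replicates
  multiply by 10^N(0, 0.1).
- **Tracks**: 50 bp bins; H3K27ac adds a Gaussian bump (height 5,
  σ 150 bp) at the TSS of expressed genes; H3K36me3 a linear ramp
  (0.5 → 3.0, 5′→3′) over bodies of expressed-or-methylated genes
  with exponential decay (length constant 1 kb, truncated at 2 kb so
  blocks cannot bridge the ≥ 3 kb intergenic gaps) into the 3′
  flank; sparse background blobs (one bin in five, exponential
  heights) provide the block population against which the top-2.5%
  selection operates. Replicates redraw blobs and jitter amplitudes.

What the generator does **not** emulate: sequence composition and
mappability biases, PCR duplicates, M-bias, fragment-length
structure, chromatin-input background correlated between replicates,
isoform switching, and realistic gene-length or GO-term
distributions. Passing recovery tests therefore demonstrates the
correctness of the estimators under the assumed noise model, not
robustness to every artefact of real libraries.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script run at ~200 genes
(~20,000 CpGs, six samples, coverage 30) for recovery panels and
3 × 80 genes for null panels — sizes at which every Monte-Carlo
tolerance below is comfortably resolved while the full suite stays
fast. Tolerances: gene-level methylation recovery is checked at the
95% level of the ±3-point band implied by the binomial SE of a
≥ 20-CpG gene at coverage 30 across three replicates; planted-DMR
recovery requires mean interval Jaccard ≥ 0.8 at ρ = 0.05; four-way
category recall ≥ 95% at default noise; profile signatures must place
the H3K27ac maximum at the TSS bin (± 1), the H3K36me3 maximum at
the TES-edge bins, and the minimal 9-bin body window of the
methylated/expressed methylation profile at the TSS edge. Exact
identities (transition marginals, BH formula, hypergeometric vs
enumeration) are asserted to machine precision.

## Known limitations

- The DMR caller controls the false-positive rate through
  permutation calibration, whose granularity is bounded by the
  number of label permutations times candidates; with 2 vs 2 designs
  the pool can be too small for q < 0.05 at realistic candidate
  counts.
- Peak consolidation scores merged regions by the first replicate's
  AUC (bookkeeping only); downstream analyses use intervals, not
  scores.
- The hypergeometric and Fisher tests assume exchangeable genes;
  gene length and CpG density confounders are not modelled.
- GO ancestor propagation requires a caller-supplied ancestor map;
  no OBO parsing is built in.
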