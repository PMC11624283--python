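# Methods

## The scientific setting

The pipeline models a paired human resistance-exercise study: muscle
biopsies at Pre and at 30 min, 3 h, 8 h and 24 h of recovery, with bulk
RNA-seq at every timepoint and RRBS methylomes for a Pre/post-exercise
contrast. The analytical claim being tested is directional: early
promoter/CpG-island *hypo*methylation marks genes that will be
*up*regulated hours later. Every statistic below is built to quantify that
coupling.

## Differential methylation

Per-sample Bismark coverage files give methylated/unmethylated read counts
per CpG (1-based coordinates; the redundant percent column is recomputed
from counts on read). Samples are **pooled into their condition groups**
to maximize genome coverage; a CpG survives filtering only if its pooled
coverage is ≥ `min_reads` (default 10) in *every* group and it is covered
in ≥ `min_samples_per_group` (default 1) samples per group. Regions —
CpG islands, or strand-aware TSS ± 1 kb promoters when only TSSs are
supplied — pool the counts of their surviving CpGs and are tested once
each with a **two-sided Fisher exact test** on the 2×2 pooled table. The
two-sided p sums all hypergeometric tables (fixed margins) whose
probability does not exceed the observed table's; it is evaluated by
direct log-gamma enumeration, which the test suite checks against both
`scipy.stats.fisher_exact` and an exact-arithmetic oracle.

Multiple testing is Benjamini–Hochberg (the `fdr_method` hook accepts any
statsmodels method name; the SLIM estimator used by methylKit is not
reimplemented — BH is the conservative standard choice). Peaks are
regions with q < 0.05 and |Δmethylation| ≥ 25 percentage points; both
thresholds are configuration, since common methylKit practice rather than
a single canonical value governs them. Peaks are tagged hypo (condition B
lower) or hyper and written as BED (0-based half-open; all coordinate
conversions are centralized in `methyltide.io`).

## Regulatory potential and target inference

Each peak within `window` = 100 kb of a gene's TSS contributes
`exp(-(0.5 + 4·d/window))` to that gene's score `s_g`; `d` is the
strand-independent distance from the **peak midpoint** (configurable to
nearest edge; neither convention is canonical) to the TSS, and the window
boundary is inclusive. The score is additive over peaks, strictly
decreasing in each peak's distance, bounded by `k·e^{-0.5}` for `k`
contributing peaks, and invariant under translating all coordinates.

Group-level inference: the one-tailed two-sample **Kolmogorov–Smirnov
test** compares the scores of upregulated (or downregulated) DEGs against
non-DEG background genes, with the alternative that group scores are
stochastically greater (group CDF below background CDF). The asymptotic
one-sided p-value is used; groups smaller than 5 fall back to the exact
method with a warning. Zero-score genes are retained in both samples;
with very sparse peak sets the resulting ties make the test conservative,
which is why the null-calibration study (below) plants dense peaks.

Gene-level inference: among DEGs passing the `df` filter (adjusted
p < 0.05), the `da` = 500 genes with the highest regulatory potential are
ranked twice — descending score (average ties) and ascending DE
significance (adjusted p, ties broken by |log2FC| descending then gene
id, because adjusted-p ties are common). With normalized ranks
`u1 = rp_rank/n`, `u2 = de_rank/n`, the rank product `x = u1·u2` has the
exact null distribution of a product of two independent uniforms,
`P(X ≤ x) = x(1 − ln x)`; targets are genes with p < `c` = 0.05. The `df`,
`c` and `da` semantics follow the BETA command-line conventions; all three
are exposed as configuration. By default the integration runs on all
peaks plus hypo-only and hyper-only strata.

## Differential expression stand-in

Normalization is median-of-ratios: reference genes are those nonzero in
every sample, and a sample's size factor is the median ratio of its
counts to the per-gene geometric mean. Rescaling one sample's library by
`c` moves the geometric-mean reference by `c^{1/n}`, so the invariant
property is scale-free: relative size factors shift by `c` for that
sample only and normalized matrices agree up to one global constant.

DE per timepoint versus Pre is a **negative-binomial Wald test**:
log2FC of normalized group means with a 0.5 pseudocount; per-gene
dispersion `α` by pooled method of moments `(s² − m)/m²` (floored at
1e-8); delta-method standard error from the NB variance `μ + αμ²`; the
Wald statistic is referred to a t distribution with `n_A + n_B − 2`
degrees of freedom, which keeps the type-I error near nominal at n = 8
where the moment dispersion estimate is noisy. BH adjusts within each
contrast. This is deliberately *not* a DESeq2 clone — no shrinkage, no
outlier refitting, no independent filtering; real-data users can inject
DESeq2 output as TSV (`read_de_table`) and the rest of the pipeline is
unchanged. The default design is unpaired per timepoint; a
subject-mean-centering flag (`paired=True`) provides a simple paired
surrogate, and neither mode is claimed to replicate any particular
published design formula.

Collapsed DEG lists are unions over post-Pre timepoints of significant
up- (down-) calls; a gene significant in opposite directions at different
timepoints appears in both lists and is flagged biphasic. Trajectory
clustering z-scores per-gene timepoint means (subject-level values would
be an alternative; means were chosen for interpretability) and cuts an
average-linkage Euclidean agglomerative tree at a user-supplied number of
clusters.

## Enrichment and temporal profiles

Gene-set enrichment is a one-sided (over-representation) Fisher exact
test, i.e. the hypergeometric upper tail, against a user-supplied
background universe of detected genes; set members outside the universe
are trimmed first, and BH runs across the collection. The temporal
profile of a set expresses the number of its collapsed DEGs significant
at each timepoint as a percentage of the set's collapsed membership
(peak timepoint = argmax, earliest on ties); percentages are reported to
one decimal in tables and rounded to integers in summaries.

## Fiber-type interpolation

%Type-I fiber area is regressed (OLS) on the MYH7/(MYH1+MYH2) normalized
transcript ratio over a reference cohort with histology; new samples are
interpolated along the fitted line and clamped to [0, 100]%. Rows with
MYH1+MYH2 = 0 are rejected by name. Recovering the published correlation
(r ≈ 0.72) requires the external reference cohort's table; the shipped
tests use synthetic references and verify exact recovery in the noiseless
case and slope/intercept recovery within 2 standard errors under jitter.

## Synthetic-data generator

The generator is the package's test bed and defines its reference study
conditions. Defaults: 4000 genes on one 400-Mb chromosome (≈100-kb TSS
spacing, jittered slots, guaranteeing distinct ordered TSSs), 10% planted
DEGs with trajectory archetypes early/late/sustained/biphasic (biphasic =
up at 30 min/3 h, down at 24 h), 37.5% of DEGs (150 genes) additionally
coupled to a hypomethylated CpG island whose midpoint lies within 50 kb
of the TSS. Coupled genes are forced upregulated with an early or
sustained archetype, modeling the hypomethylation→upregulation axis.
Islands carry 10–30 CpGs over 200–1500 bp; coupled islands start at
55–90% methylation so a 40-point hypo shift stays in range (out-of-range
shifts are clamped with a warning); ~5% of non-coupled genes get
unshifted islands (specificity controls) and ≥10% of islands sit in a
gene-free tail > 100 kb from every TSS (negative controls).

RRBS counts: per CpG and sample, coverage ~ Poisson(50) and methylated
count ~ Binomial(coverage, island p); zero-coverage CpGs are emitted as
0/0 and removed by the pooling filter. RNA-seq counts: gene baselines are
lognormal (log-mean log 200, log-sd 1), each of 8 subjects carries a
lognormal multiplier (log-sd 0.15) shared across its timepoints — the
paired-biopsy structure — and counts are NB with dispersion 0.05 via the
gamma–Poisson mixture, with planted log2FC 1.5 effects per archetype.
Where no published value exists for a generator parameter (RRBS depth
model, NB dispersion, subject variability), these are one-time choices of
realistic magnitudes, recorded here and not tuned.

What the generator does **not** emulate: read-level data, bisulfite
conversion error, CpG-density covariates of methylation, length/GC biases
of RNA-seq, library-size heterogeneity beyond subject multipliers, and
correlated gene modules. Passing tests therefore demonstrate correctness
of the statistics and recoverability of planted signals under idealized
noise, not performance on real tissue data.

## Calibration studies and problem sizes

`methyltide.calibration` runs the operating-characteristic studies used
by the tests and the acceptance script:

* **KS null** — replicates use a compact genome (300 genes, 30 Mb) with
  densely planted shifted islands whose placement is independent of the
  randomly drawn "DEG" labels: coupling is absent by construction while
  scores remain effectively continuous. Per-timepoint DE is not re-run in
  these replicates because, with labels drawn independently of the
  methylome, the label mechanism is exchangeable regardless of how labels
  would have been estimated. Rejection at α = 0.05 sits near 0.05.
* **Planted recovery** — 20 seeded full-pipeline runs at the reference
  conditions; the up-vs-background KS p and the fraction of planted genes
  in the top-500 regulatory-potential list are recorded.
* **DE null and power** — 2000-gene null matrices at n = 8/group for the
  raw-p rejection rate, and planted log2FC-3 genes at baseline 500 for
  power.

The replicate genome sizes above are deliberate scale-downs of the
reference scenario chosen so the studies remain cheap to re-run while
leaving the per-test sample sizes (reads per CpG, subjects per group)
at their reference values.

## Numerical choices and degenerate inputs

* Coverage files are 1-based inclusive; BED is 0-based half-open; the
  conversion lives in `methyltide.io` only.
* Percent methylation is undefined (NaN) at zero coverage; such sites
  never reach a test.
* A region whose surviving CpGs vanish is omitted, not zero-filled;
  duplicated region ids are an error.
* An empty peak set skips the KS test with a warning rather than failing
  the run; an empty non-DEG background (a df = 1.0 filter) does the same.
* BH uses standard step-up with stable gene ordering; rank ties in the
  rank product average (scores) or break deterministically (DE).
* Determinism: every random draw flows from explicit seeds
  (`numpy.random.default_rng`); rerunning a pipeline config reproduces
  byte-identical TSVs, which the test suite checks by checksum.

## Known limitations

* BH in place of methylKit's SLIM correction changes q-values; rankings
  of regions are unaffected.
* The NB Wald stand-in is anti-conservative for very low counts and does
  not shrink fold changes; use external DESeq2 tables for publication-
  grade DE on real data.
* The one-tailed KS p is approximate under heavy score ties (sparse peak
  sets): conservative in practice.
* The rank-product null assumes the two rankings are independent, which
  holds under the no-coupling null but only approximately when the da
  filter has already selected on one of them.
* Fiber-type estimates are clamped extrapolations outside the reference
  ratio range.
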