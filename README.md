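# methyltide

Methylome–transcriptome integration and time-course transcriptome analytics
for skeletal-muscle exercise biology.

Acute resistance exercise remodels the muscle DNA methylome within minutes
and the transcriptome over the following day. A central analytical question
is whether early promoter/CpG-island methylation changes *predict* which
genes are up- or downregulated hours later. `methyltide` implements a
complete, testable pipeline for that question, aimed at exercise
physiologists and epigenomics analysts working with RRBS + bulk RNA-seq
time courses:

1. **RRBS differential methylation** — Bismark coverage files are pooled
   per condition (minimum 10 reads per base, covered in ≥1 sample per
   group), promoters or CpG islands are tested with a two-sided Fisher
   exact test on pooled counts, BH-corrected, and significant regions are
   exported as **methylation peaks** (hypo/hyper), playing the role of
   transcription-factor binding peaks.
2. **BETA-style integration** — each peak within 100 kb of a gene's TSS
   contributes a distance-decayed weight to the gene's regulatory
   potential

   $$s_g = \sum_{i=1}^{k} e^{-(0.5 + 4\Delta_i)},\qquad
     \Delta_i = d_i / 100\,\mathrm{kb},$$

   group-level inference compares score distributions of up- (down-)
   regulated DEGs against non-DEG background with a one-tailed
   Kolmogorov–Smirnov test, and gene-level targets are called by the rank
   product of the regulatory-potential and differential-expression ranks,
   with the exact p-value $p = x(1-\ln x)$ for the product of two
   independent uniform ranks.
3. **Time-course transcriptomics** — median-of-ratios normalization, a
   negative-binomial Wald test per post-exercise timepoint versus Pre (a
   documented DESeq2 stand-in; external DE tables can be ingested
   instead), collapsed 24-h up/down DEG lists (biphasic genes appear in
   both), z-score trajectory clustering, background-corrected Fisher
   gene-set enrichment, and per-set temporal proportion profiles.
4. **Fiber-type interpolation** — %Type-I fiber area is interpolated from
   the MYH7/(MYH1+MYH2) transcript ratio along an OLS standard curve fit
   to a histology reference.
5. **Synthetic-data generator** — plants known DMR–DEG couplings,
   trajectory archetypes (early/late/sustained/biphasic) and enriched gene
   sets so every stage is validated end to end without downloads.

## Worked example

Simulate the reference study (4000 genes, 150 planted hypomethylated
promoter islands coupled to upregulated genes, 40-point methylation shift,
log2FC 1.5, 50× RRBS coverage, 8 paired subjects), call peaks, run DE at
3 h, and integrate:

```python
import methyltide as mt

design = mt.SyntheticDesign(seed=7)
genes, islands, truth = mt.generate_annotation(design)
tables, groups = mt.generate_methylome(islands, design)
dm = mt.DifferentialMethylation().fit(
    tables, groups, islands.rename(columns={"island_id": "name"}))
counts, metadata = mt.generate_counts(truth, design)
de = mt.differential_expression(counts, metadata, "3h")
beta = mt.BetaIntegrator(direction_mode="combined").fit(
    genes[["gene_id", "chrom", "tss", "strand"]], dm.peaks_, de)
print(beta.results_["combined"].summary())
```

prints

```
BETA-style integration [combined peaks]
    up: n=248 vs background n=3628  D=0.5915  one-tailed p=1.87e-71
  down: n=124 vs background n=3628  D=0.0081  one-tailed p=0.979
    up targets called: 13 / 248
  down targets called: 3 / 124
```

All 150 planted coupled islands are called as hypomethylation peaks, the
KS test detects that upregulated DEGs carry far more methylation-peak
regulatory potential than background (p ≈ 1.9e-71) while downregulated
DEGs do not (p ≈ 0.98), and all 150 planted genes land in the top-500
regulatory-potential list. The same stages are available as a CLI:

```bash
methyltide simulate --out sim/ --seed 7
methyltide meth --cov-dir sim/coverage --groups sim/groups.tsv \
    --regions sim/islands.bed --out meth/
methyltide de --counts sim/counts.tsv --metadata sim/metadata.tsv --out de/
methyltide integrate --peaks meth/peaks_all.bed --tss sim/tss.bed \
    --de de/de_3h.tsv --df 0.05 -c 0.05 --da 500 --window 100000 --out beta/
methyltide run-all --out run/ --seed 7      # everything, one manifest
```

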