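# zdose

Dosage compensation and dosage balance analysis for ZW sex-chromosome
systems.

In birds and other female-heterogametic (ZW) taxa, females carry a single
Z chromosome. Without compensation, female expression of Z-linked genes
drops to half the ancestral level (Z_f:AA_f = Z_f:ZZ_m = 0.5); most birds
show only *partial* compensation (ratios between 0.5 and 1), and the
regulatory mechanism — chromosome-wide chromatin accessibility vs local
5mC methylation centres — is an open question. `zdose` implements the
statistical toolkit for this question end to end, exercisable entirely on
synthetic data with known generative truth:

* **Ratio statistics** — per-gene log2(f:m) = log2(median FPKM_F / median
  FPKM_M), sex-specific Z:A ratios, balance classification
  (fully / partially / intermediate / unbalanced at |log2 f:m| cut points
  0.25 / 0.5 / 0.75, sex bias at |v| > 2), percentile bootstrap CIs, and
  four-level group models (AA_f, AA_m, Z_f, ZZ_m or PAR x sex) with
  covariates and case-bootstrap CIs.
* **Chromatin accessibility** — orthologous peak clustering (reciprocal
  50% overlap, ≥ 2 samples), consensus peaks (80% share), peak-to-gene
  assignment (gene ± 20 kb; TSS/TTS ± 1 kb regulatory scope), f:m
  peak-height ratios, functional annotation of the highest peak, and a
  permutation differential-accessibility test (cpm > 1 in ≥ 7 samples).
* **5mC methylation** — CpG-island calling (> 250 bp, GC > 60%,
  CpG O/E > 0.75), coverage-filtered (≥ 10 reads) cumulative-count feature
  methylation, bootstrap f:m divergence, beta-binomial sex-effect
  regression with BH correction, and peak-flank methylation profiles.
* **Z-chromosome scans** — Fisher exact enrichment/depletion of balanced
  genes in PAR-sized (688 kb) and 1-Mb sliding windows and 15-gene blocks
  with Bonferroni correction, Wilcoxon peak-height window tests, and
  autocorrelation along the Z.
* **PAR detection** — two-segment change-point on autosome-normalised
  log2(f:m) DNA coverage, reconciled with the extent of female
  heterozygosity.
* **Synthetic data** — a generator for the whole study (genome + PAR,
  expression with per-gene compensation factors c_g ∈ [0.5, 1], ATAC
  peaks with a female-Z height multiplier, beta-binomial methylation,
  ploidy-structured coverage) in the standard file formats (BED,
  narrowPeak, Bismark coverage, bedGraph, TSV).

The model and its assumptions are documented in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a small study (2 autosomes + Z, 60 genes, 8 females / 7 males)
and run the expression analysis:

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_expression_dosage.py --seed 1
```

which prints:

```
wrote study to results/study: 60 genes (20 on chrZ), 15 samples, ...
true mean compensation factor on non-PAR Z: 0.633
60/60 genes pass the mean-FPKM >= 1 filter
balance classes: {'fully_balanced': 35, 'partially_balanced': 15, 'unbalanced': 6, 'intermediate': 4}
Zf:AAf (linear) = 0.622
ZZm:AAm (linear) = 1.117
median log2(Zf:ZZm) = -0.526 [-1.032, -0.251] over 15 genes (linear 0.694)
model AAf:AAm = 1.003 [0.958, 1.049]
model Zf:ZZm = 0.709 [0.609, 0.817]
```

Reading the output: the generator placed a mean compensation factor of
0.63 on the non-PAR Z, and both the empirical estimate (Z_f:AA_f = 0.62)
and the model-based dosage-balance ratio (Z_f:ZZ_m = 0.71 with its 95% CI)
recover partial compensation — between the pure dose effect (0.5) and
full compensation (1) — while the autosomal control ratio AA_f:AA_m sits
at 1 as it must. The remaining drivers analyse chromatin accessibility
(`03`), methylation (`04`), scan the Z for regional clustering (`05`) and
locate the PAR boundary (`06`); each prints its findings and writes TSV/JSON
tables under `results/`.

A thin CLI wraps the same pipeline: `zdose run --seed 1 --out results/run`
executes every stage on a simulated study and writes a manifest; `zdose
simulate` writes the raw study files.

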