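# Methods

`zdose` re-implements, as a tested pipeline over synthetic data, the
statistical machinery used to quantify dosage compensation and dosage
balance on an avian (ZW) Z chromosome from three molecular layers: gene
expression (RNA-seq), chromatin accessibility (ATAC-seq peak heights) and
5mC methylation (bisulfite counts), together with a sliding-window scan for
regional regulation and detection of the pseudo-autosomal region (PAR).

## The dosage model

In a ZW system, females carry one Z; without compensation, female
expression of Z-linked genes halves, giving Z_f:ZZ_m = Z_f:AA_f = 0.5.
Full compensation restores 1. The generative model makes this explicit:
the expected expression of gene *g* in sample *s* is

    E[y_gs] = baseline_g x copies(g, s) x c(g, s)

with copies = 2 everywhere except 1 on the female non-PAR Z, and
c = 2·c_g on the single female Z copy (1 otherwise). The per-gene
compensation factor c_g ∈ [0.5, 1] is then exactly the linear-scale f:m
expectation: c_g = 0.5 is a pure dose effect, c_g = 1 full compensation.
Compensation acts multiplicatively on the single female copy precisely so
that this identity is analytic rather than approximate.

Ratios are estimated two ways, as in the study design:

* **empirical** — per gene, log2(median FPKM in females / median FPKM in
  males); chromosome summaries are medians over genes with percentile
  bootstrap CIs over genes (default 10,000 replicates);
* **model-based** — a four-level group model (AA_f, AA_m, Z_f, ZZ_m; or
  the PAR x sex analogue) on the transformed response (log2 for expression
  and peak height, arcsine-square-root for methylation proportions), with
  standardized covariates. The default fit is a two-stage estimator
  (feature-level cell means, then precision-weighted level means); a REML
  linear mixed model with variance components for feature and individual
  (statsmodels `MixedLM`) is provided as a cross-check, and the two agree
  within 2% on balanced designs (tested). Ratios are always formed after
  the exact back-transform (2^x, sin²x), and bootstrap CIs come from
  case-resampling features and refitting (default 1,000 replicates).

Per-gene log2(f:m) values are partitioned into dosage-balance classes:
fully balanced (|v| ≤ 0.25), partially balanced (0.25 < |v| ≤ 0.5),
intermediate (0.5 < |v| < 0.75) and unbalanced (|v| ≥ 0.75), with sex bias
flagged beyond |v| > 2. The published interval wording leaves (0.5, 0.75)
unassigned and is not a total partition; the explicit "intermediate" class
closes it, boundaries fall to the less extreme class, and a three-class
scheme (unbalanced at |v| ≥ 0.5) is available for sensitivity analysis.

## Expression processing

FPKM = counts x 10^9 / (gene length x library size). Two expressed-gene
filters mirror the study: a mean-FPKM filter (kept iff mean FPKM ≥ 1 in
females **and** males; exactly 1 is kept, only strictly-below is dropped)
and a zFPKM filter: per sample, x = log2 FPKM over positive values, the
mode located by Gaussian KDE, the spread estimated from the right
(actively transcribed) tail as a half-Gaussian, σ = mean(x[x>μ] − μ)·√(π/2),
and genes kept at z > −3; the modelling set is the intersection over
samples.

## Chromatin accessibility

Libraries are binomially thinned to the smallest library's total.
Orthologous peaks are clusters (connected components) of peaks overlapping
reciprocally by ≥ 50% of each peak's length and present in ≥ 2 samples;
within-sample duplicates keep the highest peak. The 50% overlap is read as
reciprocal — the stricter interpretation, preventing chains of small peaks
attaching to large ones — with a single-sided option. Consensus peaks keep
clusters present in ≥ 80% of samples and merge retained clusters
overlapping ≥ 50%. Peaks link to genes at two scopes: gene-centred (body
± 20 kb) and regulatory (strand-aware 1 kb upstream of the TSS / 1 kb
downstream of the TTS, excluding the gene body). Each gene's highest
linked peak (ties broken toward the TSS) is annotated by summit location
with priority TSS > TTS > exon > intron > intergenic; the summit is the
narrowPeak offset when present, else the interval midpoint.

Differential accessibility on counts-in-peaks uses a label-permutation
test: peaks kept at cpm > 1 in ≥ 7 samples, statistic = difference of mean
log2(cpm + 0.5) between sexes, exhaustive permutation when the label
arrangements fit the budget, Monte-Carlo with the add-one correction
otherwise, BH across peaks. This intentionally replaces a
negative-binomial GLM with a distribution-free test of the same effect
direction and filters.

## 5mC methylation

CpG islands are called by a deterministic threshold scan: 200-bp windows
stepped 1 bp scored for GC fraction and CpG O/E = (#CG x L)/(#C x #G);
qualifying windows (GC > 0.60, O/E > 0.75) are merged, merged segments are
trimmed 1 bp per side until the whole segment passes both composition
thresholds, and segments are reported only if longer than 250 bp and
re-verified against all three thresholds. Every reported island is
re-checkable directly from sequence (tested), and calls are invariant to
flanking-N padding up to the coordinate shift.

Feature methylation is the cumulative-count proportion Σmeth/Σtotal over
CpGs with ≥ 10 reads (optionally relaxed to 5 on the Z for the single-copy
female chromosome), after removing masked positions (transition-SNP and
repeat masks are consumed as BED); a feature with no retained CpG is
missing, never 0. Sex divergence per feature: samples resampled within sex
(10,000 replicates), reporting the median and 2.5/97.5 percentiles of both
log2(f:m) and (f − m); a male proportion of zero flags the log scale while
(f − m) is still reported.

Differential methylation fits, per feature, a beta-binomial by maximum
likelihood with a logit-linear mean (intercept + sex, optionally tissue)
and one dispersion per feature (intra-class correlation ρ, lower bound
10⁻⁶ against boundary failures), testing the sex coefficient with a Wald
statistic and BH correction. The ρ → 0 limit reproduces the binomial
likelihood to 10⁻⁶ (tested). Standard errors come from the observed
information over the mean coefficients at the fixed dispersion estimate:
inverting the full Hessian fails exactly when ρ̂ hits its bound and
inflates SEs under near-separation, costing real power. Wald p-values are
approximate at few samples (empirically ~0.12 instead of 0.05 at p < 0.05
with 4 + 4 samples, approaching nominal by 20 + 20); the null-control
guarantee the pipeline relies on is at the BH-q level, where the false
discovery fraction stays below 0.05 (tested on 2,000 null features).

## Z-chromosome scans

Window schemes: coordinate windows of the PAR size (688 kb) stepped half a
PAR, or 1 Mb stepped 100 kb, the last window truncated at the chromosome
end; and disjoint blocks of 15 expressed genes (the PAR's expressed-gene
count), final partial block flagged. Per window, a two-sided Fisher exact
test on the 2x2 table (balanced vs not x in-window vs out), computed
directly from the hypergeometric pmf and equal to the scipy reference to
10⁻¹⁰ (tested); Bonferroni over the windows of one (chromosome, scheme)
family — conservative given overlapping windows, accepted as such.
"Compensated" defaults to the fully-balanced class, configurable to
fully ∪ partially. Peak-height windows use Wilcoxon tests (rank-sum on
pooled heights by default, signed-rank on per-peak medians as an option)
with one-sided alternatives available; windows where fewer than 3
individuals of either sex have non-zero values are untested. The ACF scan
reports sample autocorrelations at lags 1..max_lag with ±1.96/√n bounds.

## PAR detection

Coverage windows per sex are normalised by that sex's autosomal median
depth; the Z-track log2(f:m) is expected near 0 in the diploid PAR and −1
in the hemizygous remainder. The study read the boundary visually; here it
is formalised as the least-squares two-segment constant fit over windows
(exhaustive over split points — equality with brute-force search is a
tested property), requiring left − right mean ≥ 0.5 in log2 units (half
the expected 1 → 0.5 ploidy drop); no qualifying split returns a "no PAR"
result rather than an error. The heterozygosity boundary is the position
after the last female-heterozygous site. The consensus takes the
heterozygosity boundary when it agrees with the coverage change-point to
within one window, else the coverage boundary with a discrepancy flag —
a documented choice; the two evidence lines have no stated precedence.

## What the generator emulates — and what it does not

Defaults are the study's conditions: 8 female / 7 male individuals, two
tissues, a Z whose PAR ends at 687,785 bp (the female-heterozygous SNP
interval bound), ~7 ATAC peaks per expressed gene, female-Z peak heights
multiplied by 1.12, methylation means 0.66 in gene bodies, 0.20 in CpG
islands, ~0 inside peaks, and ploidy-structured coverage. The per-gene
compensation mixture (28% fully, 19% partially, 53% uncompensated, weights
from the reported balance-class counts) yields a mean c̄ ≈ 0.63. Where the
study is silent the standard generative families were chosen once:
log-normal expression baselines with negative-binomial counts (dispersion
0.08), log-normal peak heights, beta-binomial methylation (ρ = 0.05),
Poisson read counts per coverage window (150-bp reads). Counts scale with
gene length, so FPKM recovers the baseline exactly; the recorded nominal
library sizes are used for FPKM in ratio analyses because at desk scale
the Z is ~half the simulated transcriptome and column-sum normalisation
would import a sex-composition bias ~6x larger than any real genome's.
Randomness is fanned out from one master seed into named substreams per
(layer, sample): layers are independently reproducible.

Not emulated: read-level artefacts (mappability, GC bias, M-bias),
isoforms, peak-calling noise beyond height jitter and drop-out, linkage
between layers beyond shared coordinates, and real between-individual
structure. Passing tests therefore demonstrate that the *estimators*
recover known generative truth under the study's statistical structure —
not that the biological conclusions transfer to any particular dataset.

## Problem sizes and numerical choices

The test-suite simulations are sized to be decisive yet quick: 500-gene
chromosomes for ratio recovery (±0.05 bands), 200 datasets x 10,000
bootstrap replicates for CI calibration (94–95% observed), 1,000 null
replicates for the Fisher-scan family-wise error (≤ 0.05), 2,000 null
features for the DML false-discovery check, 40 seeds for change-point
localisation. The male Z:A parity check uses common random numbers (one
baseline draw shared between Z and autosomes by gene rank) so that the
±0.05 band tests the statistic's identity rather than the ~8% sampling
noise of a median ratio over 500 iid log-normal baselines. Bootstrap point
estimates are the bootstrap-distribution median with 2.5/97.5 percentile
CIs; per-sex medians with even sample counts use the midpoint convention;
Fisher two-sided p sums hypergeometric point probabilities ≤ the observed
one (with the customary 1 + 10⁻⁷ tolerance factor); optimizer for the
beta-binomial is Nelder-Mead polished by BFGS.

## Known limitations

The mixed-model option treats individual and feature as crossed variance
components in a single group and is slow for large feature counts — the
two-stage estimator is the workhorse, with the mixed fit as a
verification path. Wald DML p-values are anti-conservative at very small
sample counts (see above). The island caller is a threshold scanner, not
an HMM; segment boundaries differ from HMM-based callers in low-contrast
regions. The PAR consensus rule prefers heterozygosity only within one
window of the coverage step, so a noisy change-point can shift the
reported boundary by a window or two. FPKM/zFPKM are the only supported
expression units.
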