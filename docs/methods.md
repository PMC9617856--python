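# Methods

This note documents the models implemented in `cfmedip`, the synthetic
cohort generator the test suite runs against, the numerical choices made
where the design was genuinely open, and the limits of what passing tests
demonstrate about real plasma data.

## Coordinate and counting conventions

All coordinates are 0-based half-open; BED is written unchanged. A
sequenced fragment `[s, e)` is assigned to the single 300 bp bin containing
its midpoint `floor((s + e) / 2)`, so every fragment is counted exactly
once and boundary-spanning fragments never double-count. RPKM uses the
total fragment count as library size:
`rpkm = count / (bin_kb * lib_millions)`. The analysis universe ("non-low"
bins) keeps a bin iff its RPKM strictly exceeds 5 in at least one sample of
the cohort under analysis; train/test workflows must pass training samples
only, and the classifier recomputes the filter inside every fold.

CpG-enrichment QC is a relH-style ratio: CpG dinucleotides per base across
all sequenced fragment intervals divided by the genome-wide CpG density.
The assay itself never defines its enrichment statistic precisely, so the
formula is fixed here and reported alongside the QC table.

## Fragmentomics

The longer-fragment ratio is `#len in [170, 210] / #len in [100, 210]`,
both bounds inclusive (tested exactly at 100/170/210); an empty denominator
yields a missing value, never zero, so downstream tests drop rather than
bias samples. Fragmentation profiles are DELFI-style short/long count
ratios (short 100–150 bp, long 151–220 bp, configurable) in 5 Mb windows
assigned by midpoint; windows without long fragments are missing and the
per-sample summary is the sample SD (ddof = 1) over non-missing windows.
No GC correction is applied to the profiles.

## Per-bin variance decomposition

Each bin's RPKM across samples is regressed on one covariate by OLS;
adjusted R² is `1 - (1 - R²)(n - 1)/(n - 1 - p)`. "Explained by LDH
independent of %ctDNA" is operationalized as
`adjR²(signal ~ ctDNA + LDH) - adjR²(signal ~ ctDNA)`; covariates with
|r| > 0.999 are rejected as collinear. Negative adjusted R² values are kept
(not clipped). Category cutoffs are strict: > 0.2 weak-to-moderate, > 0.5
moderate-to-high. Annotation enrichment uses Fisher's exact test (sample
odds ratio ad/bc, Haldane–Anscombe 0.5 correction with a flag on zero
cells) and a permutation test whose null — overlap counts of |selected|
bins drawn uniformly without replacement from the background — is sampled
directly from the exactly-equivalent hypergeometric distribution rather
than by materializing permutations; the empirical p uses the add-one rule.

## Differential methylation

Counts are modeled per bin as NB2:
`K_ij ~ NB(mu_ij, alpha_i)`, `log mu_ij = log s_j + x_j' beta_i`.

- **Size factors**: median-of-ratios over bins with nonzero counts in every
  sample, rescaled to geometric mean 1.
- **Dispersion**: per-bin method of moments on size-factor-normalized
  counts with within-class pooling (so planted class effects do not inflate
  alpha), floored at 1e-8. No shrinkage toward a mean-dispersion trend is
  applied; at the 30-per-class scale the suite runs at, the raw
  type-I error is within [0.03, 0.07] (measured across 10 seeds).
- **Fit**: IRLS vectorized across bins (shared design, batched 3x3/4x4
  solves), 50 iterations, convergence at max |d beta| < 1e-6;
  non-convergent bins are flagged and assigned p = 1, never dropped
  silently.
- **Inference**: Wald z on the class coefficient, two-sided normal p,
  Benjamini–Hochberg q across tested bins. A DMR requires q < 0.05 and
  |log2 FC| > 1 (fold change > 2), without posterior shrinkage of the fold
  change — the simplest reading of the threshold.

The hyper:hypo risk score divides the per-sample mean RPKM over hyper-DMRs
by the mean over hypo-DMRs (RPKM rather than raw counts, to remove
library-size confounding); the cohort median splits high/low, ties go to
"low". Kaplan–Meier curves and the 1-df log-rank test come from lifelines;
a group with zero events is reported non-estimable. The pericentromeric
summary averages normalized signal over differential bins intersecting the
centromere gap ± 1 Mb (closed at the flank edges).

## Diagnostic classifier

Each of 50 repeats draws `n_per_class = 21` patients per class (training
uses one sample per drawn patient, earliest timepoint, deterministic);
the test set is one sample per remaining patient. Non-low filtering, size
factors, the NB Wald test (age and batch as covariates when the fold
supports them — batch enters the design directly; no surrogate-variable
step), DMR calling and information-gain ranking all run inside the fold.
Information gain is computed in bits on fold-normalized `log2(K/s + 1)`
signal with candidate thresholds at midpoints of consecutive distinct
values, ties toward the smaller threshold; it is verified against
exhaustive split enumeration. Test samples are normalized by projecting
onto the training reference (median ratio to the training per-bin geometric
mean), so no test statistic leaks into fitting; an instrumented test
asserts no test sample id reaches the fold's fitting routines. The
classifier is a 500-tree random forest; AUROC uses the rank statistic with
mid-rank ties. The label-permutation null harness shuffles class labels at
the patient level and relaxes the "zero DMRs is an error" contract so the
~0.5 null accuracy is measurable.

## Copy-number inference

Bin signal (counts per million) is summed into 250 kb windows. The window
size is a deliberate choice: the three smoothing scales are fixed at
3/15/51 windows, and an iterated median filter annihilates any feature
shorter than about half its width, so on a 30 Mb toy chromosome the
51-window scale is only meaningful if a chromosome spans well over 100
windows. 250 kb gives 120-window chromosome tracks while keeping ~5
heterozygous SNPs per window at the simulated 50 kb SNP spacing. Windows
are log2-ratioed against the localized reference cohort's median (+1
pseudocount), median-centered per sample, and smoothed per chromosome to a
fixed point (max 30 passes; edge windows shrink).

Each scale is decoded by a 3-state HMM with Gaussian emissions at
(-mu, 0, +mu) and common sigma; EM re-estimates mu and sigma from
mu0 = 0.3 and the track MAD with transitions fixed at a 0.99
self-transition prior; decoding is Viterbi (verified against exhaustive
path enumeration). Two evidence guards render the "correct predictions
with relatively low evidence" idea concrete, and both are config keys:

1. If the EM amplitude lands below `min_amplitude = 0.1` log2 — the size of
   a one-copy event at roughly 15% tumor fraction — the scale's track
   carries no interpretable copy-number signal and is reported all-neutral
   with a flag. Without it, regional coverage waviness is called as CNA in
   low-tumor-fraction samples.
2. The allelic-shift correction smooths each sample's per-window mean
   |BAF - 0.5| at the same three scales and fits a 2-component Gaussian
   mixture per scale on the *log* deviation (allelic shifts act
   multiplicatively on the deviation, so baseline-versus-shifted separates
   at every tumor fraction, whereas on the natural scale the mixture
   isolates only the stronger loss cluster at high fractions). A window is
   "shifted" when the higher-mean component's posterior exceeds 0.5 *and*
   the deviation clears the neutral component's mean + 2 SD.

Consensus: each of the 9 (methylation scale x BAF scale) combinations votes
a window's HMM state if the state is non-neutral and either that BAF scale
marks the window shifted or the smoothed |log2 ratio| exceeds 0.4; a final
non-neutral state needs >= 6 votes (with BAF absent each methylation scale
casts 3 identical votes, so >= 6 means >= 2 of 3 scales agree). CNA
coverage is the non-neutral window fraction; gene-level comparison takes
the majority window state per gene (ties neutral) and excludes genes with
no overlapping window.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
raw sequence. Expected bin signal per sample is

`mu = depth * [(1 - f) * m + f * t] * c * cov * bias`

with `m` a CpG-density-driven baseline profile (20% of bins scaled low so
the non-low filter has work to do; assembly-gap bins zeroed), `t` the tumor
profile (`m` times 2^3 at planted hyper bins — chosen so the observed class
contrast after dilution by the metastatic fraction distribution is about
+1.9 log2, comfortably above the fold-change gate), `c = (2 + f*clon*delta)/2`
over planted CNA segments, `cov` the LDH/ALP covariate effects (100 bins
each, slope 0.5 per SD of the log covariate, drawn independently of `f`)
and `bias` a spatially correlated coverage waviness (ln-SD 0.035,
correlation length ~4 Mb) that median filtering cannot remove — the
realistic reason low tumor fractions are hard. Counts are gamma-Poisson
with dispersion 0.1. Metastatic samples additionally scale planted hypo
bins by 2^(-2.5 * TME), where the per-sample TME intensity ~ Beta(2, 1.2)
is independent of `f`: hypomethylation of repeat/pericentromeric bins
models a tumor-microenvironment source, reproducing both the absence of a
hypo-signal/%ctDNA correlation and the existence of genuinely hard
(low-f, weak-TME) metastatic samples that the classifier misclassifies.

ctDNA fractions: localized ~ Beta(1.5, 30) (mean ≈ 0.05), metastatic ~
Beta(2, 3) truncated at 0.9 (mean ≈ 0.4, range matching the reported
metastatic regime); explicit per-sample fractions can be supplied for
titration designs. Hyper-DMRs are planted preferentially (80%) in
CpG-island bins and hypo-DMRs in repeat/pericentromeric bins, so annotation
enrichment has signal. Fragment lengths mix N(187, 25) (normal) and
N(155, 22) (tumor, weight f) truncated to [60, 400] bp — synthetic values
placed so the 170–210/100–210 ratio is discriminative; the tumor component
mean additionally varies by 5 Mb window (SD 10 bp), which raises the
fragmentation-profile SD with tumor burden. SNP B-allele fractions are
Beta-distributed (concentration 100) around `(1 + f_e*delta) / (2 + f_e*delta)`
inside CNA segments (`f_e = f * clonality`; affected allele random), 0.5
elsewhere. CNA segments default to 3 clonal arm-scale events of 9–15 Mb
per metastatic sample (shorter events cannot survive the fixed 15/51-window
smoothing scales on a 90 Mb genome and would make the stated consensus
unreachable by construction); localized samples are copy-neutral because
they serve as the reference cohort. A titration design (one shared tumor
genome, clonality 1.0/0.6/0.35, fractions on a grid) provides the
dose-response setting for the coverage-versus-f association. Survival
times are exponential with hazard `h0 * exp(beta * z(risk))`, `h0 = 1/30`
per month, `beta = 1.5`, and an independent exponential censoring clock
calibrated to a 30% censoring probability; the planted risk score is the
standardized tumor fraction.

All randomness flows from one master seed through `SeedSequence` spawns
(plan / sheet / survival / one stream per sample), so equal seeds give
byte-identical cohorts.

## Problem sizes used by the test suite and acceptance script

The package's validation runs at desk scale by design: differential
testing and classification use 2-chromosome 350 kb genomes (~2,300 bins,
~1,900 non-low) with 30 + 30 or 30 + 60 samples and 10 harness repeats;
copy-number suites use the full default 3 x 30 Mb genome (~360 windows of
250 kb) with 8–12 metastatic samples; fragmentomics uses 2 x 3 Mb genomes
with 8,000 fragments per sample. These sizes preserve the statistical
regimes (per-bin counts, per-window SNP density, samples per class) of the
full-scale analysis while keeping the suite fast and deterministic.

## Limitations

The generator draws counts directly at bin level, so the fragment tables
and the count matrix are statistically consistent but not derived from one
another; read-level artifacts (GC bias, mappability, duplicate structure,
batch-specific enrichment efficiency) are not modeled, and passing recovery
tests therefore demonstrates correctness of the statistical machinery, not
robustness to those artifacts. Absolute methylation levels are out of
scope — the assay yields relative enrichment only. Exact numerical parity
with the original study's patient-data results (DMR counts, 0.989
classification accuracy, 0.86 panel-sequencing concordance) is not
claimed; those require the access-restricted cohorts, and this package
asserts the directional and recovery properties instead.
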