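# cfmedip

Analysis of plasma cell-free DNA (cfDNA) methylomes profiled by cfMeDIP-seq
(immunoprecipitation of methylated cfDNA followed by sequencing), built for
the comparison of localized versus metastatic prostate cancer liquid
biopsies. The package implements the full downstream pipeline on top of
aligned fragments, together with a synthetic ctDNA-mixture cohort generator
with planted ground truth, so every stage can be validated by parameter
recovery without access-restricted patient data.

## What it computes

Plasma cfDNA is a mixture: a fraction *f* (the circulating-tumor-DNA
fraction, %ctDNA) comes from the tumor, the rest mostly from blood cells.
The pipeline quantifies methylation enrichment in 300 bp genomic bins
(fragments assigned by midpoint, RPKM-normalized, restricted to "non-low"
bins with RPKM > 5 in at least one sample) and then asks, stage by stage:

- **Fragmentomics** — the longer-fragment ratio
  #fragments in [170, 210] bp / #fragments in [100, 210] bp (lower in
  tumor-rich samples) and DELFI-style short/long fragment-count profiles in
  5 Mb windows, whose genome-wide standard deviation rises with tumor burden.
- **Covariate variance decomposition** — per-bin adjusted R² of the signal
  on clinical covariates (%ctDNA, LDH, ALP, age), the adjusted-R² increment
  ΔR² of LDH over a ctDNA-only model (tumor-microenvironment signal), and
  Fisher/permutation annotation enrichment of the explained bins.
- **Differential methylation** — per-bin negative-binomial GLM
  `K_ij ~ NB(mu_ij, alpha_i)`, `log mu_ij = log s_j + x_j' beta_i` with
  median-of-ratios size factors, method-of-moments dispersion, age/batch
  covariates, a Wald test on the class contrast and Benjamini–Hochberg
  correction; a DMR is a bin with q < 0.05 and |log2 FC| > 1. The
  per-sample hyper:hypo ratio risk score (mean RPKM over hyper-DMRs divided
  by mean over hypo-DMRs) feeds median-dichotomized Kaplan–Meier / log-rank
  survival analysis.
- **Diagnostic classification** — 50 repeats of: draw 21 + 21 patients per
  class, rediscover DMRs inside the fold, rank hyper/hypo candidates by
  information gain, keep the top 150 of each, fit a 500-tree random forest,
  evaluate on one sample per held-out patient. Reported as median accuracy,
  median AUROC and per-sample misclassification frequency versus %ctDNA.
- **Copy-number inference** — window-level log2 ratios against the localized
  reference cohort, iterated median smoothing at 3/15/51-window scales, a
  3-state HMM (loss/neutral/gain) per scale, a B-allele-fraction Gaussian-
  mixture allelic-shift correction, and a consensus that requires at least
  6 of the 9 scale-combination votes. Summarized as CNA coverage (fraction
  of non-neutral windows) and per-gene confusion against truth.
- **Performance metrics** — one-vs-rest sensitivity/specificity/precision/
  accuracy/F1 from confusion counts, macro averages, rank-based AUROC.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from cfmedip.simulate import SimulationParams, build_genome_model, simulate_cohort
from cfmedip.quantify import rpkm, filter_nonlow
from cfmedip.dmr import nb_wald_test, call_dmrs, hyper_hypo_ratio
from cfmedip.survival import km_logrank

params = SimulationParams(n_localized=30, n_metastatic=30,
                          n_chromosomes=2, chrom_length=350_000,
                          centromere_gap=60_000, island_spacing=30_000,
                          n_hyper=60, n_hypo=60, n_fragments=1000,
                          cna_segments_per_sample=0,
                          libsize_log_mean=float(np.log(40_000)))
genome = build_genome_model(params, seed=3)
cohort = simulate_cohort(genome, params, seed=3)

mat = filter_nonlow(rpkm(cohort.matrix))
print(f"non-low bins: {len(mat.counts)} of {len(cohort.matrix.counts)}")

dmrs = call_dmrs(nb_wald_test(mat, cohort.sheet))
print(f"hyper-DMRs: {len(dmrs.hyper)}  hypo-DMRs: {len(dmrs.hypo)}  "
      f"ratio: {dmrs.count_ratio}")

scores = hyper_hypo_ratio(mat.rpkm, dmrs)
met = cohort.sheet.df.query("`class` == 'metastatic'")["sample_id"]
rho = spearmanr(scores.loc[met, "score"], cohort.truth.f[met]).statistic
print(f"risk score vs true ctDNA fraction (metastatic): Spearman rho = {rho:.2f}")

km = km_logrank(scores["group"],
                cohort.sheet.column("os_time"), cohort.sheet.column("os_event"))
print(f"high vs low risk score, overall survival: chi2 = {km.chi2:.2f}, p = {km.p:.2g}")
```

Output:

```
non-low bins: 1932 of 2334
hyper-DMRs: 59  hypo-DMRs: 48  ratio: 1.2
risk score vs true ctDNA fraction (metastatic): Spearman rho = 0.73
high vs low risk score, overall survival: chi2 = 18.36, p = 1.8e-05
```

The DMR caller recovers nearly all 60 + 60 planted effects with almost no
false calls; the hyper:hypo score tracks the samples' true tumor fractions;
and because simulated survival hazard is tied to tumor burden, the
median-split of the score separates the survival curves.

## Command line

A thin CLI wraps the library:

```bash
cfmedip simulate --seed 1 --out-dir cohort/
cfmedip dmr      --sheet cohort/samples.tsv --counts cohort/cohort --out dmrs.tsv
cfmedip classify --sheet cohort/samples.tsv --counts cohort/cohort --seed 1 --out perf.tsv
cfmedip cna      --sheet cohort/samples.tsv --counts cohort/cohort --seed 1 --out cna.tsv
```

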