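# Methods

## Scope and model of the problem

`exprqc` performs phase-three quality control of quantitative sequencing
experiments: QC on the *expression matrix*, after read-level checks
(FastQC-type) and alignment-level checks (RSeQC/QoRTs-type) have passed.
The failure modes it targets are sample-level: a library that collapsed
during preparation, GC-dependent amplification bias, cross-sample
contamination, and technical covariates (library protocol, flow cell, RNA
extraction method) that drive more variance than the biology under study.
No single statistic identifies these reliably, so the tool computes an
ensemble of views over the same matrix and lets the analyst — or a
deliberately conservative flagging heuristic — read them jointly.

Sample membership is controlled exclusively by the phenotype sheet:
columns of the count matrix absent from the sheet are dropped (with a
warning). Re-running a QC or downstream analysis without a suspect sample
is therefore a one-line edit of the sheet.

## Normalizations

**TPM** (human/mouse with a gene annotation):
`TPM(g,s) = (c(g,s)/l(g)) / Σ_g' (c(g',s)/l(g')) × 10⁶` with `c` the read
count and `l` the annotated gene length in bp. Genes without an
annotation entry are excluded before the rate sums and listed in the
result's provenance, so the retained columns sum to exactly 10⁶. When the
annotation is partial this renormalizes over the annotated subset; the
alternative (keeping unannotated genes with a pseudo-length) was rejected
as it silently distorts the unit.

**Size-factor transform** (other organisms): median-of-ratios size
factors — `sf(s) = median_g c(g,s)/geomean(c(g,·))` over genes positive in
every sample — followed by `log2(count/sf + 1)`. This is a deliberate
approximation of a full dispersion-trend variance-stabilizing transform:
it preserves the property that matters here (cross-sample comparability
of depth-corrected values) while staying free of fitted hyperparameters.
The method tag `vst_like` and the factors are recorded in provenance.

**Row z-scores** for normalized PCA: `(x − μ)/σ` per gene across samples
with the *population* standard deviation, so every non-constant row has
mean 0 and variance 1 exactly. Zero-spread rows become all-zero rows
(keeping matrix shape stable for PCA) and are counted in provenance.
z-scoring is applied to the `log2(count+1)` matrix: on the raw count
scale a gene's cross-sample profile is dominated by its magnitude, and
standardizing log-expression is what makes "every gene weighs the same"
meaningful.

**`log2(x+1)`** is the shared display/distance transform behind the box
plot, clustering, correlations (default) and all gene profiles.

## The QC surface

*Summary statistics* per sample, on the raw count scale: number of gene
rows ("detected genes", constant across samples by construction), mean,
SD (ddof = 1), median, min, max, range, skewness, kurtosis, library size
(exact column sum) and expressed genes (count > 0). Skewness and kurtosis
are the population moment estimators `g1 = m3/m2^1.5` and
`g2 = m4/m2² − 3`, defined as 0 when `m2 = 0`; conventions differ across
ecosystems, so these are fixed and documented rather than configurable.
Quartiles (box statistics, on `log2(count+1)`) use linear interpolation.

*Mapped-read density*: Gaussian KDE of `log2(normalized value + 1)` per
sample, Silverman bandwidth, a shared 512-point grid spanning the global
range padded by three times the widest bandwidth (so each curve
integrates to ≈ 1). An all-constant sample gets a flagged flat placeholder.

*Housekeeping and gene profiles*: GAPDH/ACTB (human) or Gapdh/Actb
(mouse), resolved through bundled symbol + Ensembl-id aliases, plotted as
`log2(count+1)` of **raw** counts. This is intentional: within-sample
normalization (TPM) cancels library depth, which is exactly the signal a
depressed housekeeping profile carries. Any other matrix can be passed
explicitly. Unresolvable ids skip the metric with a pointer to the manual
gene lookup (which also strips Ensembl version suffixes and falls back to
case-insensitive matching).

*PCA*, samples as observations, gene variables centered but not rescaled:
run once on the z-scored matrix (biology-weighted view) and once on raw
counts, where library-size differences deliberately dominate PC1 — the
mechanism by which a depth-collapsed sample separates. Component signs
follow a largest-|loading|-positive convention for reproducibility.
Variance-explained fractions over all `min(n−1, p)` components sum to 1.

*MFA*: variable groups are the z-scored expression block plus one block
per categorical covariate, expanded to centered one-hot indicators scaled
by `1/√(level frequency)` (the multiple-correspondence convention). Each
group's variables are divided by the square root of its own first
eigenvalue — inverse-first-eigenvalue weighting, so every group enters
with leading variance 1 — and a global PCA of the concatenation yields
sample scores. Per-group contributions to a component are the sums of
squared loadings over the group's variables (they sum to 1 per
component). Covariate attribution compares contributions *among
covariate groups*: a covariate that fully drives expression ties the
expression block at 0.5 by construction, so the expression block is
reported but not ranked against covariates. Constant covariates are
dropped with a warning; with no usable covariate the analysis returns a
skip marker that the report records (not an error).

*Hierarchical clustering* of samples: Euclidean distance over
`log2(count+1)` genes, complete linkage by default (`--linkage`
overrides). *Correlation heatmaps*: Pearson and Spearman (average ranks)
over a configurable input matrix (default `log`), exactly symmetrized,
with leaf order from Ward linkage on `d = 1 − r`; zero-variance samples
get NaN rows and are listed as undefined.

*GC-bias curves*: per sample, LOWESS of `log2(count+1)` against gene GC
fraction over the counts∩annotation genes (≥ 20 required). LOWESS is
tricube-weighted local linear regression over the `int(frac·n)` nearest
neighbours, `frac = 2/3`, 3 bisquare robustness iterations (classic
Cleveland settings; `--lowess-fraction` overrides). For n > 200 points
the standard interpolation shortcut (delta = 1% of the x-range) is used;
below that every point is fitted exactly. The y-axis is log-scale counts
rather than raw counts to keep the fit stable across the expression range.

## Outlier flagging

Each rule computes a robust z-score `(x − median)/(1.4826·MAD)` (falling
back to the scaled mean absolute deviation if the MAD degenerates) of one
per-sample statistic and triggers past 2.5:

| rule | statistic | direction |
|---|---|---|
| `low_library_size` | library size | below −2.5 |
| `low_housekeeping` | mean of the two housekeeping profiles | below −2.5 |
| `extreme_pc1` | un-normalized PC1 score | beyond ±2.5 |
| `depressed_gc_curve` | mean fitted GC-curve height | below −2.5 |

Rule hits are advisory and all reported; a sample is *called* an outlier
only when ≥ 2 distinct rules agree. Rationale: with a handful of samples
a robust z past 2.5 on a single statistic is common by chance (the MAD of
7 well-behaved values is a noisy scale estimate), while technical defects
are systemic and trip several depth-linked statistics at once. Flags
never remove a sample; exclusion is the analyst's edit of the phenotype
sheet. With fewer than 4 samples the rules are skipped (median/MAD
meaningless).

## Synthetic data generator

Counts are negative binomial:
`counts(g,s) ~ NB(mean = L_s · μ_g · exp(β_group + γ_cov + slope_s·(gc_g − 0.5)), α_g)`.

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genes; two housekeeping rows planted first |
| `groups` | control×4, diseased×4 | the two-phenotype design |
| `log_mu_mean`, `log_mu_sd` | 5.0, 1.5 | lognormal per-gene baselines (median ≈ 150 counts, heavy right tail; library ≈ 0.9 M) |
| `dispersion`, `dispersion_mean_scale` | 0.05, 5.0 | NB dispersion trend `α(μ) = α0 + α1/μ`: replicate-level CV ≈ 22% for high genes, larger for low ones; set `dispersion_mean_scale = 0` for constant dispersion |
| `group_effect_sd`, `group_gene_frac` | 0.5, 0.1 | differential expression between groups |
| `library_scale` | {} | per-sample depth multipliers (0.05 = collapsed library) |
| `gc_slope` | {} | per-sample multiplicative GC term `exp(slope·(gc − 0.5))` |
| `bio_noise`, `bio_gene_frac` | {}, 0.15 | per-sample symmetric log-space expression shifts on a gene subset |
| covariates | [] | per-level lognormal shifts on a gene fraction |

Housekeeping rows get high (`log_mu_mean + 3`), tight (ln-sd 0.1)
baselines and are exempt from group, covariate and bio-variability
effects — they still feel library scale and the GC term, which is why
their profile exposes depth problems. Gene lengths are discretized
lognormals ≥ 200 bp; GC fractions are Beta(5, 5). Per-sample biological
variability is planted outside the top 1% of baseline expression:
constitutive top expressors are stable between individuals, and a
variable-but-healthy sample should scatter on equal-weight views of the
data, not on depth-dominated ones.

Presets: **A** clean (false-positive control); **B** one sample with a 5%
library and a GC slope of −2 plus one biologically variable sample
(`bio_noise` 0.8); **C** three growth-condition groups with a strong
2-level protocol covariate (sd 1.0 on 30% of genes) and a moderate
3-level flow-cell covariate (sd 0.4 on 20%); **D** two cell types crossed
with an extraction-protocol covariate whose effect (sd 1.2 on 40%)
exceeds the cell-type effect.

What the generator does *not* emulate: transcript-level structure
(lengths and GC are independent of expression), correlated gene modules,
zero-inflation beyond what the NB produces, and count matrices from
pseudo-aligners with non-integer expected counts. Passing tests
demonstrate that the metrics recover planted artifacts of realistic
magnitude under NB sampling noise — not that the flag thresholds are
calibrated for any particular real dataset.

## Numerical choices and edge cases

- TPM raises on a sample with zero counts over annotated genes; the
  size-factor transform raises when no gene is positive in every sample.
- Duplicate gene ids (possible with symbol input) are rejected with the
  offending ids listed, never summed or averaged silently. Ensembl `.N`
  version suffixes are stripped on read (toggleable).
- PCA/MFA determinism: sign convention as above; scikit-learn's exact SVD
  solver at these sizes is deterministic, and TSV outputs are written
  with a fixed `%.10g` format, so identical inputs give byte-identical
  outputs.
- Dendrogram merge heights with complete linkage are monotone
  non-decreasing; other linkages are accepted but may invert.
- Tied Spearman ranks use average ranks. Correlation matrices are exactly
  symmetrized (`(C + Cᵀ)/2`, unit diagonal reimposed).

## Problem sizes used in the shipped checks

The packaged test-suite and `scripts/acceptance.py` run the synthetic
scenarios at their default size (2000 genes × 8–12 samples), with 100
seeds for the outlier-recovery and false-positive rates and 50 for the
covariate-attribution rates; oracle comparisons (brute-force PCA,
exhaustive agglomeration, naive local weighted least squares) use small
fixtures (4–5 samples, 20–50 points) where the naive O(n²)–O(n³)
re-derivations are exact and fast. These sizes were chosen so the whole
battery completes in well under a minute while keeping binomial noise on
a 100-seed rate below ±5 points.

## Known limitations

- The size-factor transform is not a dispersion-trend VST; for organisms
  without annotation the density plot's tails are wider than DESeq2's
  `vst` would give.
- Housekeeping resolution covers human and mouse only; other organisms
  use the manual gene lookup.
- The flagging heuristic is tuned for ≥ 4 samples and two-ish groups; in
  heavily unbalanced designs robust z-scores across *all* samples mix
  groups and can mask a within-group outlier.
- MFA treats covariates as categorical; continuous covariates must be
  binned by the user.
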