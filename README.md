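# exprqc

Expression-based quality control for RNA-seq (and other count-based
sequencing) experiments.

Read-level QC tells you whether base calls are good; alignment-level QC
tells you whether mapping worked. Neither reliably catches a sample whose
*library* went wrong — a collapsed library, GC-dependent amplification
bias, cross-sample contamination, or a technical covariate (protocol,
flow cell, extraction method) that drives more variance than the biology.
`exprqc` works on the quantified gene-by-sample count matrix, where these
problems are visible, and computes the ensemble of views an analyst needs
to call an outlier with confidence:

- per-sample **summary statistics** (detected/expressed genes, moments,
  library size) and a counts-distribution box plot;
- **mapped-read density** after TPM (human/mouse, given a gene
  annotation) or a median-of-ratios size-factor transform (other
  organisms): `TPM(g,s) = (c_gs/l_g) / Σ_g' (c_g's/l_g') × 10⁶`;
- **housekeeping profiles** (GAPDH, ACTB) on the depth-bearing
  `log2(count+1)` scale, plus an expression plot for any gene;
- **PCA** twice — on row z-scored data (`z = (x−μ)/σ`, biology-weighted)
  and on raw counts, where depth dominates PC1 and broken samples stand
  apart;
- **multiple factor analysis**: covariate blocks weighted by the inverse
  of their first eigenvalue, attributing leading variance to protocol /
  flow cell / batch;
- agglomerative **hierarchical clustering** (Euclidean), **Pearson and
  Spearman** heatmaps with Ward leaf ordering, and per-sample **GC-bias
  LOWESS curves**;
- advisory **outlier flags**: robust z-scores (median/MAD, threshold 2.5)
  on library size, housekeeping level, un-normalized PC1 and GC-curve
  height; a sample is called an outlier when ≥ 2 rules agree. Nothing is
  removed automatically — you exclude a sample by deleting its row from
  the phenotype sheet and re-running.

Inputs are two tab-delimited files (a count matrix from RSEM / HTSeq /
featureCounts / Kallisto / Salmon, and a phenotype sheet with `sample`,
`group` and optional covariate columns), plus an optional gene annotation
(`gene_id`, `length_bp`, `gc_fraction`) enabling TPM and the GC metric.

## Worked example

The package ships a negative-binomial simulator with planted artifacts
(`exprqc.simulate`). Preset `B` reproduces the canonical failure mode:
eight samples in two groups, where `control4` has a 5% library and a
depressed high-GC response, and `diseased3` is biologically variable but
technically sound.

```sh
exprqc --demo B --seed 1 --outdir qc_out
```

prints

```
potential outlier sample(s): control4
mfa skipped: no covariate column in the phenotype sheet
QC outputs written to qc_out
```

and writes the summary table, one TSV per metric, the figure set and a
`report.json` manifest. The summary table shows the low-expression
signature (control4's library is ~5% of its group, with far fewer
expressed genes):

```
sample     detected_genes  mean     median  max    library_size  expressed_genes
control3   2000            476.98   138.5   42504  953957        1984
control4   2000             25.97     6.0    3567   51933        1535
diseased1  2000            491.41   144.5   51644  982811        1979
```

`outlier_flags.tsv` shows all four rules agreeing on control4 (robust
z-scores far past the 2.5 threshold) while diseased3 trips at most a
single advisory rule and is not called:

```
sample_id  rule                statistic   threshold
control4   low_library_size      -39.04    2.5
control4   low_housekeeping      -22.03    2.5
control4   extreme_pc1           -26.01    2.5
control4   depressed_gc_curve   -256.59    2.5
```

On real data, replace the demo flags with your files:

```sh
exprqc --counts counts.tsv --pheno pheno.tsv --annotation genes.tsv \
       --organism human --gene MYC --outdir qc_out
```

To re-run the whole QC without a suspect sample, delete its row from
`pheno.tsv` and run the same command again — columns missing from the
phenotype sheet are dropped automatically.

The same surface is available as a library (`exprqc.run_qc`, or the
individual functions `tpm`, `pca_samples`, `mfa`, `gc_bias`, ... on
pandas DataFrames).

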