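# protscape

Tools for integrating heterogeneous, MS1-quantified proteomics studies into a
single protein-expression landscape, and for the downstream analyses such a
landscape supports: tumour-specific peptide discovery, cell-line/tumour
similarity, mRNA–protein concordance and ranked gene-set enrichment.

## Who this is for

Public proteomics repositories hold many label-free (iBAQ-quantified) cancer
studies — cell-line panels and clinical tumour cohorts — acquired in
different labs on different instruments. Aggregating them promises a
reference map of protein expression across lineages, but the raw iBAQ
matrices carry strong study-of-origin batch effects and substantial
missingness. `protscape` implements a tested, reusable version of the
integration procedure, together with a synthetic multi-study generator with
full ground truth, so every step can be validated by recovery experiments
rather than by eye.

## The method

Starting from MaxQuant-style `proteinGroups.txt` tables (iBAQ columns,
trypsin-digested assays only) and SDRF-like sample annotations, each side of
the dataset (cell lines; tumours) is taken through:

1. **ppb scaling** — each protein's iBAQ in assay *j* is scaled by that
   assay's total observed signal:
   `ppb_i = (iBAQ_i / Σ_i iBAQ_i) × 100,000,000`,
   making assays compositionally comparable (each observed column sums to
   10⁸ exactly).
2. **log2 transform** and a **presence filter** keeping proteins quantified
   in ≥ 50 % of assays (inclusive boundary).
3. **Missing-value imputation** — iterative rank-*k* SVD by default
   (initialize with per-protein means, overwrite only missing entries with
   the rank-*k* reconstruction, iterate to tolerance); limit-of-detection
   and local-least-squares imputation are provided for benchmarking.
4. **Batch removal** — per protein, an OLS linear model of abundance on the
   study-of-origin covariate; the fitted batch component is subtracted while
   preserving each protein's grand mean and all within-batch contrasts.

The two corrected matrices are merged by leading razor protein accession
(exact match first, isoform-stripped second). Downstream modules compute
pairwise-complete Pearson/Spearman sample correlations, per-lineage CVs,
within-sample and gene-wise (BH-adjusted) mRNA–protein Spearman
correlations, a lineage × study ANOVA with Tukey HSD, a preranked weighted
Kolmogorov–Smirnov gene-set enrichment statistic with permutation NES/p/FDR,
and validation diagnostics (per-study density summaries, PCA + k-means
adjusted-Rand batch assessment, anchor-protein correlation against absolute
copies-per-cell abundances, imputation RMSE benchmark).

## Worked example

```python
import protscape as ps

cfg = ps.GeneratorConfig(n_proteins=500, n_studies=3, seed=7)
raw, annotation, truth = ps.generate_multistudy(cfg)
corrected = ps.run_normalization(raw, annotation)

rna = ps.generate_paired_rna(truth, cfg)
cells = annotation.table[annotation.table.sample_type == "cell_line"]
prot = corrected.values[list(cells.index)]
prot.columns = [cells.loc[a, "sample_id"] for a in prot.columns]
paired = ps.PairedOmics(protein=prot, rna=rna)
within = ps.within_sample_rna_protein(paired)
across = ps.across_sample_rna_protein(paired, min_overlap=5)
```

With this seed the run prints:

```
raw matrix: 500 proteins x 24 assays, 14.1% missing
normalized: 449 proteins, stage: batch_corrected
between-study location spread: 0.871 -> 0.022 log2 units
median within-sample mRNA-protein r_s: 0.496
median gene-wise r_s: 0.280; 1 genes significant at q<0.01
```

Reading: the generator planted per-study global intensity offsets (the
0.87-log2 spread between study medians of the raw data); after ppb scaling,
SVD imputation and batch removal the spread is ~0.02. The presence filter
kept 449 of 500 proteins. The within-sample correlation (0.50 here) sits
below its configured target of 0.58 because it is measured on the *observed*
(noisy, imputed, corrected) matrix of only 12 cell-line assays; measured on
the true abundances at the scale the recovery tests use (6,000 genes, 30
samples), the target is recovered within ±0.02. With only 12 samples per
gene, few of the ~0.3-correlated genes clear the q < 0.01 bar — gene-wise
significance needs the ~134-sample scale.

A shell interface wraps the same functions:

```sh
protscape simulate --seed 7 --proteins 500 --out-dir run/
protscape normalize --in run/raw_ibaq.tsv --sdrf run/sdrf.tsv --impute svd --out run/norm.tsv
protscape all --seed 7 --out-dir run_full/   # end-to-end with manifest
```

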