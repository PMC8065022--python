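# Methods

This note documents the models and procedures implemented in `protscape`,
the assumptions they make, the parameters that matter, and the design
choices taken where the design was genuinely open.

## Data model and stage discipline

Quantification data live in an `IntensityMatrix`: proteins × assays with NaN
for missing values and a *stage* tag (`raw_ibaq → ppb → log2_ppb → imputed →
batch_corrected`). Every pipeline operation checks the stage of its input
and refuses out-of-order application; this is the cheapest way to make "the
batch model assumes log-scale additivity" and "imputation requires the
filtered log2 matrix" enforceable rather than conventions.

Zero iBAQ values are read as *missing*, not as measured zeros: the upstream
quantification tool reports an undetected protein as 0, and treating those
as real measurements would poison both the composition scaling and the
imputation.

## Normalization

**ppb scaling.** Each observed value is divided by its assay's total
observed signal and multiplied by 10⁸. The denominator sums observed values
only — with missingness present this is the only computable reading, and it
gives the exact invariant tested throughout: each assay's observed values
sum to 10⁸. The scaling is compositional; it removes global
loading/instrument-scale differences but nothing protein-specific.

**Presence filter.** Proteins observed in ≥ 50 % of assays (inclusive
boundary, denominated in MS runs) are kept, applied separately per side
(cell lines / tumours) before merging. The threshold is configurable.

**SVD imputation.** Iterative low-rank completion: missing entries start at
per-protein means; each iteration replaces only the missing entries with the
rank-*k* SVD reconstruction; convergence is declared when the relative
Frobenius change of the imputed entries falls below the tolerance.

- *Rank* defaults to `min(5, min(dim) − 1)` — enough to capture
  lineage-level structure in the synthetic recovery tests; it must be chosen
  by the user for real data.
- *Tolerance* defaults to 1e-4 with at most 500 iterations. Convergence of
  the iteration is geometric but slow (reaching 1e-6 can take thousands of
  iterations on realistic matrices) and changes of order 1e-4 in imputed
  log2 entries are far below measurement noise; the exactness tests pass
  tighter tolerances explicitly. (The reference R implementation of this
  algorithm defaults to a much looser 1e-2.)

LOD imputation (per-assay minimum observed value) and local least squares
(OLS of each incomplete protein on its *k* most correlated complete
proteins over the target's observed columns, with intercept) are provided as
benchmarking alternatives; `imputation_benchmark` reports per-method RMSE on
masked entries against synthetic truth.

**Batch removal.** Per protein, an OLS model of log2 abundance on the batch
covariate (study of origin) is fitted and the fitted batch component
subtracted, with the constraint that the protein's grand mean is preserved;
equivalently, batch means are collapsed onto the grand mean while all
within-batch deviations are kept exactly. In balanced designs this coincides
with a sum-to-zero-contrast parameterization; in unbalanced designs the
grand-mean-preserving form is used because it keeps the corrected matrix's
per-protein location identical to the input, which downstream CV and
correlation analyses rely on. No biological covariates are protected: the
model contains batch only, and a design in which batch is perfectly
confounded with lineage or sample type is rejected rather than "corrected".
A single-batch input is returned unchanged with a warning.

Batch correction is applied *within* each side only; the merged
cell-line/tumour landscape deliberately carries any residual cross-side
scale difference, because almost no samples are shared across sides and a
cross-side batch term would be unidentifiable.

## Merging

Sides are merged on leading razor protein accessions in two passes: exact
accession, then isoform-suffix-stripped (`P05-2 → P05`) for the leftovers.
When stripping creates duplicate razor keys within one side, the protein
group with the larger total intensity is kept (logged). Unmatched proteins
are retained with missing values on the absent side; no quantification
value is altered by merging.

## Peptide landscape

All peptide analyses are presence/absence. A peptide is *tumour-only* if
detected in at least one tumour assay and no cell-line assay; only peptides
whose mapped protein set has cardinality 1 are used for protein calls
(uniqueness is taken from the evidence table as given, not recomputed from
sequences); a protein is *tumour-specific* if it carries tumour-only unique
evidence **and** no peptide of any kind mapping to it was seen in a cell
line. Majority detection per group uses the inclusive ≥ 50 % boundary.
Group-set intersections use exclusive (UpSet-style) semantics, so the counts
partition the union — an invariant the tests enforce.

## Concordance statistics

- Sample–sample correlations are computed on pairwise-complete observations
  (per pair, rows observed in both assays), Pearson on log2 intensities with
  Spearman available alongside. Pairs with fewer than 10 complete rows
  (configurable) are reported undefined — below that the coefficient is
  noise.
- CV (%) is computed on the linear scale, back-transforming `2**x` from the
  final log2 matrix, per protein per group with ≥ 2 observed values.
- Within-sample mRNA–protein concordance: one Spearman per proteomics assay
  across genes. Replicate assays remain separate observations; mRNA
  replicates are expected pre-averaged. mRNA enters rank statistics as
  given; Pearson-type uses go through `log2(FPKM + 1)`.
- Gene-wise concordance: Spearman per gene across samples,
  Benjamini–Hochberg adjusted across genes, significance reported at
  adjusted p < 0.01. Constant genes are excluded from the adjustment.
- The lineage analysis fits a two-way fixed-effects ANOVA of per-assay r_s
  on lineage and study (main effects only — an interaction is not
  identifiable with the typical unbalanced designs), after excluding
  lineages with fewer than 3 assays, followed by Tukey HSD on lineages.

## Preranked enrichment

The enrichment score is the extremum of the weighted Kolmogorov–Smirnov
running sum (hit increment `|score|^w / Σ_hits |score|^w`, miss decrement
`1/(N − m)`); weight defaults to 1, and weight 0 makes the statistic
invariant under monotone score transforms. Ties between the positive and
negative extremum are broken toward the positive value (with a 1e-12 float
tolerance). Because the input is a preranked list, the null is gene-set
permutation: random same-size sets on the same list. NES divides ES by the
mean |null ES| of matching sign; the nominal p is the matched-sign tail
fraction (0 meaning "beyond permutation resolution"); FDR q is the standard
ratio of null-NES to observed-NES tail fractions, clipped to [0, 1].
Gene-set input is GMT. 1,000 permutations and a mandatory seed are the
pipeline defaults.

## Validation diagnostics

- `density_profiles` summarizes each study's pooled value distribution and
  reports the maximum absolute difference between study medians — the
  quantitative surrogate for "the density plots line up".
- `pca_batch_assessment` runs PCA on centered assay profiles (unit-variance
  scaling optional, off by default), k-means (k = number of label levels,
  20 restarts, fixed seed) in the top-2 component space, and scores
  agreement with study and lineage labels by adjusted Rand index. Effective
  correction shows ARI(study) > ARI(lineage) flipping to
  ARI(lineage) > ARI(study). A quantitative surrogate was needed because
  visual inspection of a PCA plot is not testable.
- `anchor_validation` correlates (Spearman) each quantification variant with
  absolute copies-per-cell abundances of anchor proteins, per assay,
  requiring ≥ 3 shared anchors; Spearman makes the check invariant to any
  monotone rescaling of the variant, which is exactly the property wanted of
  a quantification pipeline.

## Synthetic data generator

The generator is first-class, tested code; it defines the conditions under
which every recovery experiment runs.

True log2 abundance of protein *p* in sample *s* is
`base_p + lineage_{p,l(s)} + e_{p,s}` with `base` uniform over a
five-orders-of-magnitude dynamic range (≈16.6 log2 units, matching the
10²–10⁶ copies-per-cell span of absolute-abundance anchor panels),
lineage effects N(0, 0.5²) shared by all samples of a lineage, and sample
effects N(0, 0.5²) (a log2 sd of ~0.5 corresponds to the ~40–55 % linear CVs
typical of sample-to-sample variability). Observed intensity is
`2^(true + batch + noise)` with per-study global offsets N(0, 1²) by default,
optional per-protein jitter, and measurement noise N(0, 0.3²). Samples cycle
over studies so batch and lineage are not confounded by construction.

Missingness combines a logistic MNAR detection curve on true log2 abundance
(midpoint 12, slope 1 — undetectability concentrated in the bottom of the
dynamic range) applied first, then uniform MCAR (2 % default); every masked
entry carries its mechanism label in the truth object. The defaults were
chosen once to land overall missingness near the mid-teens percentage range
typical of presence-filtered aggregated matrices; per-study missingness and
batch magnitudes are free parameters, not calibrated claims.

Paired mRNA is coupled through Gaussian copulas at two levels. Across
samples within a gene, the mRNA deviations track the protein's true
deviations at that gene's target Spearman (`2·sin(π·r_s/6)` latent Pearson),
so the realized per-gene correlation converges to the configured target as
samples grow. Across genes, the gene-level mRNA baseline tracks protein
baseline abundance at the within-sample target; here the latent correlation
is inflated analytically (from configured variances only) to undo the
attenuation caused by the lineage/sample noise on the protein side and the
per-sample deviations on the mRNA side, and the innovation is orthogonalized
against the baseline scores in-sample, so the configured within-sample
Spearman is realized without generation-level drift. FPKM-like values are
`2^log2` and therefore non-negative.

Anchors are a random protein subset whose copies-per-cell are a monotone map
of true abundance onto 10²–10⁶, with optional log10 rank noise. Peptide
fixtures plant labelled classes — tumour-only unique peptides (each marking
a tumour-specific protein), tumour-only ambiguous peptides (dropped by the
uniqueness rule), unique tumour-only peptides on proteins that also carry
cell-line evidence (planted negatives for the protein call), cell-line-only
and shared background — and record all counts in the truth object.

What the generator does **not** emulate: raw spectra, retention times,
peptide-to-protein intensity rollup, correlated (protein-complex) abundance
structure, heavy-tailed intensity noise, or study-specific missingness
patterns. Passing recovery tests therefore demonstrate that the pipeline's
operations are correct under the stated statistical model, not that the
model captures every pathology of real repository data.

## Problem sizes used in the automated checks

Recovery experiments run at deliberately modest scale: batch-structure
reversal at 1,000 proteins × 24 assays (6 lineages × 4 assays, 3 studies)
over 10 seeds; anchor ordering at 300 proteins × 24 assays with 14 anchors
over 10 seeds (fully observed, protein-specific offsets of sd 1.0 — global
offsets cannot change within-assay ranks, so they cannot probe the
comparison); within-sample correlation recovery at 6,000 genes × 30
samples; gene-wise recovery at 2,000 genes × 134 samples; null calibration
of the BH step at 2,000 genes over 20 seeds; GSEA calibration with 200
random sets at 1,000 permutations. These sizes were chosen as the smallest
at which the targeted effects are comfortably resolved.

## Known limitations

- The merged landscape is not re-corrected across sides; cross-side
  comparisons inherit any residual side effect.
- LLS imputation regresses on *complete* neighbour proteins only; matrices
  with no complete rows are rejected rather than imputed progressively.
- The ANOVA treats study as a fixed effect; with many small studies a mixed
  model would be more appropriate.
- FDR q-values from the NES-ratio estimate are conservative and can be
  non-monotone across sets; they are not abstract BH q-values.
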