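# Methods

This note documents the statistical procedures `mgpde` implements, the
modeling choices made where the design was open, and what the synthetic data
do and do not establish about real data.

## Preprocessing

Counts (possibly fractional, from transcript-abundance estimators collapsed
to gene level) pass through, in order: caller-supplied id exclusion;
removal of genes gathering more than 1% of a sample's reads in more than
half of the samples (read-hoarding artifacts; decided on per-sample read
shares, hence library-size invariant); removal of genes whose expression is
below the per-sample median in at least 20% of the samples (the median is
recomputed on the matrix as it stands after the high-share filter — note
this filter is *not* idempotent, since removing genes raises the median;
it is applied once, as a single QC pass); and Tukey's-fences outlier
flagging on each sample's median Pearson correlation of log2-CPM with all
other samples (quartiles by linear interpolation; fences Q1 − 1.5·IQR and
Q3 + 1.5·IQR).  Pearson on log2-CPM is the default correlation because the
log transform already tames heavy tails; Spearman is available.  The
log2-CPM pseudocount is 1.0 on the CPM scale.

## Marker gene profiles

For one cell type with marker set M: z-score each marker gene across
samples, take PC1 of the samples × markers matrix, and orient the component
so the majority of marker loadings are positive ("main trend"; ties go to
the previous repetition's sign, positive initially).  Robustification:
repeat 100 times on subsamples containing min(n_case, n_control) subjects
drawn without replacement from each group; within each repetition drop
markers whose loading opposes the majority sign and refit on the survivors;
project **all** samples onto the repetition's component using the
subsample's centering/scale (so every sample is scored in every
repetition); standardize the repetition's scores; the per-sample median
across repetitions is the MGP.  Final columns are standardized and oriented
to correlate positively with mean z-scored retained-marker expression, so
higher MGP = higher inferred relative abundance.  Markers kept in >50% of
repetitions are reported as retained.  One RNG stream per cell type derives
from (seed, index in sorted cell-type names), making results independent of
iteration order.

MGPs are *relative* surrogates: they rank samples within a cohort and carry
no absolute cell-count scale.  Group differences are assessed two ways per
cell type: (a) OLS of MGP on group plus covariates (group coefficient and
t-test p), and (b) two-sided Wilcoxon rank-sum on residuals after removing
covariate effects (group excluded from the residualization).  Other cell
types' MGPs can join both adjustments to ask whether one type's shift is
explained by another's.

Power at the cohort scale this package targets (13 vs 13) is modest: a
composition shift of ~1 standard deviation of the between-subject proportion
spread is detected roughly half to two-thirds of the time; ≥80% power
requires a shift of about 1.3 SD (0.8 on the log-proportion scale at the
default conditions).  The acceptance checks use the latter.

## Covariate diagnostics

The pairwise correlogram encodes binary variables 0/1 and reports Pearson r
with two-sided t-test p-values; multi-level categoricals are excluded from
the correlogram (a single coefficient is undefined) but enter the PC
association as dummy-coded regressors.  PC association: PCA on
gene-standardized log2-CPM (samples as observations); each of the top PCs
is regressed on each variable separately and the F-test p reported with the
PC's variance fraction.

## Differential expression

Per gene, an NB2 GLM log μ = log s + Xβ with median-of-ratios size factors
s (normalized to geometric mean 1).  The design holds intercept, group
(control=0/case=1, so positive LFC = higher in cases), dummy-coded
categorical covariates, and centered/unit-scaled continuous covariates
including any MGP columns.  Fitting is vectorized across genes (batched
IRLS; all genes share the design).  Dispersion is estimated per gene by
maximizing the adjusted profile likelihood — the NB log-likelihood minus
½ log det(XᵀWX), the standard correction for estimated regression
coefficients — over a log-spaced grid with golden-section refinement; a
method-of-moments estimate seeds the search and serves as fallback.  No
trend or MAP shrinkage is applied; agreement with shrinkage-based NB Wald
implementations is rank-level, not gene-for-gene (verified in tests against
an independent implementation: Spearman > 0.95 on LFC and Wald statistics).

The Wald statistic for the group coefficient is referred to a t
distribution with n − p degrees of freedom rather than the normal — at
n ≈ 26 this small-sample correction is what keeps the null p < 0.05 rate at
its nominal level (measured 0.045–0.055 under the generator's global null;
the normal reference runs anti-conservative at ~0.06+).  BH FDR is computed
across tested genes, optionally after independent filtering: the
mean-normalized-count quantile threshold (grid 0–0.95 by 0.05) that
maximizes BH rejections at the analysis α, ties to the lowest threshold;
filtered genes keep their nominal p but get no FDR.

## Gene scores and enrichment

S_up = 1 − p/2 for LFC < 0 and p/2 for LFC ≥ 0; S_down = 1 − S_up; p is
clamped to [1e-300, 1] before logs.  Gene score resampling: per set
(intersected with the scored universe; effective size limited to 5–200 by
default, ermineJ-style), the observed statistic is the mean log score of
member genes; the null is the mean over n_resample (default 10 000) random
same-size draws from the universe, shared across sets of equal size; raw
p = (1 + #{null ≤ observed}) / (n_resample + 1), so the smallest attainable
p is 1/(n_resample+1); BH within each direction.  Multifunctionality
correction is not implemented.

Delta significance: Δ = log₁₀(p₀) − log₁₀(p_CT) on BH-corrected p-values,
computed only for pathways with p₀ < α or p_CT < α; zero p-values are
clamped to the resampling floor before the log.  Base 10 matches the scale
on which such deltas are conventionally reported.  Ascending order lists the
largest losses under composition adjustment first; the tail holds the
gains.  Cross-cohort replication takes sets significant in both cohorts in
the same direction; reporting groups redundant sets by single-linkage
clustering on the Szymkiewicz–Simpson overlap |A∩B|/min(|A|,|B|) > 0.5.

## Coverage QC

Inputs are per-transcript base-level coverage vectors (5′→3′) with
expression weights; BAM processing is upstream of this package.  On the
top-1000 transcripts by weight (length ≥ 200 required): bias5 = mean of the
first 100 bases over the transcript mean, bias3 likewise for the last 100,
CV = sd/mean of base coverage; per-sample metrics are medians across
transcripts, and the profile is the mean of per-transcript coverage binned
into 100 equal base-span windows and normalized to the transcript mean
(uniform coverage ⇒ bias5 = bias3 = 1, CV = 0, profile ≡ 1).  Within-cohort
linear regressions of each metric on RIN and cross-cohort Wilcoxon tests
quantify degradation sensitivity and protocol differences.

## Synthetic data

Expected counts: μ[g,s] = lib_s · deg[g,s] · Σ_c π[s,c]·σ̃[g,c] ·
2^(LFC_g·case_s), with NB sampling at constant dispersion (default 0.1).
Components:

- **Signatures** σ: log2-normal base expression (mean 5, sd 2) with
  per-cell-type spread `signature_sd` = 1.5 log2 units — most genes differ
  severalfold across brain cell types, which is precisely what turns a
  composition shift into a genome-wide confounder.  Columns are normalized
  to sum 1 (σ̃) so π mixes on a relative scale.
- **Markers**: 30 per type by default; own-type signature is base + 4 log2
  units and other-type deviations are clipped at ≤ 0, guaranteeing ≥ 16×
  specificity by construction.
- **Proportions** π: Dirichlet with neuron-dominant cortical baseline
  (0.40/0.25/0.20/0.10/0.05 × concentration 30 — the concentration encodes
  the large subject-to-subject gray/white variability of cortex
  dissections).  Cases receive an additive log-proportion (softmax) shift;
  the default disease condition is +0.5 for oligodendrocytes, and the
  confounding experiments use +1.3 (severe skew).
- **Regulatory effects**: n genes drawn disjoint from markers (so
  compositional and regulatory truth are identifiable), alternating ±LFC.
- **Degradation**: deg = exp(−γ_g·(RIN_max − RIN_s)) with γ_g ~
  U(0, strength); RIN ~ U(3.0, 7.2); default strength 0.1.
- **Cohort**: 13 cases / 13 controls, library size ~1e6 (2000 genes; a
  desk-scale stand-in for genome-wide depth), lognormal with CV 0.3; sex,
  age, PMI, two batches drawn independently of group.
- **Pathways** in three labeled flavors: composition-confounded (drawn from
  one cell type's markers), regulatory (drawn from planted DE genes of one
  direction), and null (random genes).

What the generator does **not** emulate: correlated gene-gene noise beyond
the mixture itself, isoform structure, batch-by-gene interactions,
cohort-specific dispersion trends, or markers that are themselves disease-
regulated (the overlap flag exists but defaults off).  Passing tests on this
model therefore show the pipeline's decision rules are correct and
calibrated under its own assumptions — not that any particular real cohort
is free of residual confounding.

## Simulation sizes and numerical choices

Calibration checks use 50 replicates of 2000 simulated genes (≈850 tested
after filtering) for the Wald null and 50 × 200 random sets for resampling
enrichment (n_resample = 1000; resolution 1/1001 amply resolves α = 0.05);
MGP recovery uses 20 seeds at defaults; the confounding experiment 2–3
seeds.  Because genes within a replicate share samples, rejection-rate
intervals are evaluated at a single replicate's test count rather than the
pooled count.  Dispersion is clipped to [1e-8, 30]; IRLS steps are damped
at 10 natural-log units; means are floored at 1e-10; zero-variance markers
are dropped with a warning; ties in the loading-sign majority fall back to
the previous repetition's orientation.
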