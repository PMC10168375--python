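# Methods

This note documents the statistical model, the conventions the
implementation fixes where the method description leaves them open, the
synthetic data the tests run on, and the limitations of both.

## Conformal calibration of imputed spatial expression

The framework treats a spatial gene-expression predictor as a black box.
Because the truth for *unmeasured* genes is unknowable, calibration uses the
measured panel itself: genes are split into folds (10 by default, seeded
round-robin after a shuffle of the sorted gene list), each fold is predicted
by a model fitted on the remaining folds, and the held-out
measurement/prediction pairs supply the nonconformity scores
s = |X − X̂| / U. The scalar U (cell-centric variability) is the
similarity-weighted mean squared deviation of a cell's predicted value from
its spatial neighbours', plus an intercept of 1. The intercept keeps scores
finite in expression-constant neighbourhoods and bounds every interval width
away from zero; it also means U is *not* scale-free — scores and quantiles
are only comparable within one prediction's scale, which is why calibration
and deployment must use the same predictor and preprocessing.

Design conventions fixed here:

* **U has no square root** and the intercept sits outside the weighted
  mean: U = 1 + Σ W δ² / Σ W. Weights use all genes present in the current
  prediction matrix (the CV fold's genes during calibration, the target
  genes at deployment); a zero-norm profile gets cosine 0, weight 1.
* **Neighbourhood graph**: K = 15 nearest cells by Euclidean distance;
  edges longer than Q3 + 1.5·(Q3 − Q1) of the pooled neighbour-distance
  distribution are pruned; a fully pruned cell keeps its single nearest
  neighbour so Σ W > 0 always. Distance ties break toward the lower cell
  index. A user adjacency (edge list) can replace graph and weights.
* **Ties X = X̂** contribute one score to *both* the lower and the upper
  set of their group — the sign-split conditions overlap at equality and
  dropping either side would bias sparse count data, where exact zeros are
  common.
* **Stratified groups**: genes k-means-clustered (k = k_g, 10 restarts,
  seeded) on the first 15 PCs of the transposed prediction matrix, cells
  clustered (k = k_c) per gene stratum on the first 15 PCs of the stratum's
  columns. A group with fewer than 100 scores on either side falls back to
  the pooled score sets (per side). Automatic selection searches k = 2, 3,
  … (cap 10), stopping at the first silhouette decrease, genes and cells
  independently. Genes or cells outside the calibration panel map to the
  nearest stratification centroid in the corresponding embedding.
* **Conformal quantile** is the order statistic of rank
  clamp(⌈(n+1)(1−α)⌉, 1, n) — no interpolation, so the finite-sample
  coverage argument applies verbatim. Lower interval bounds are not clipped
  at zero: predictions may live on transformed scales.
* **Coverage evaluation** uses the α grid 0.02, 0.04, …, 0.98; the
  calibration error is the trapezoidal integral of
  |empirical coverage − (1 − α)| over that grid, so a degenerate
  always-cover or never-cover interval family scores ≈ 0.48 (exactly 0.5 on
  the full [0, 1] range).

## Multiple-imputation inference

For each cell-gene entry and each of D − 1 perturbed imputations, a score is
drawn uniformly (independently per entry, with replacement) from the union
of the entry's group score sets, each side first truncated at its own
conformal quantile for α = 0.2 to temper outliers; the prediction is moved
by ±s·U according to the side the score came from. Imputation 1 is the
unperturbed prediction. Independence across entries is the simplest
exchangeable choice; it ignores spatial correlation of errors, which makes
the ensemble slightly conservative for spatially coherent error fields.

The modified two-sample t-test pools per-imputation mean differences μ_d and
pooled-variance terms s_d² into s_MI² = s_W² + (1 + 1/D)·s_B² and refers
t = μ_MI/√s_MI² to a t distribution with
df = (D−1)(1 + D·s_W²/((D+1)·s_B²))². When s_B² = 0 (all imputations
identical) the statistic degenerates to the classical pooled t-test on the
original prediction with df = n_A + n_B − 2; zero pooled variance with zero
mean difference returns p = 1. Tests are two-sided. For arbitrary
per-imputation tests (one-sided rank-sum, spatial-variability tests fed
through the generic hook) p-values are probit-transformed, combined as
z = mean(p̃)/√(1 + Var(p̃)) and mapped back; boundary p-values are clamped
at 1e−300 with a warning. One-vs-all scans apply Benjamini–Hochberg within
each label across genes (default FDR 5%).

## Downstream uses of the intervals

Cell filtering scores each cell by the mean over genes of per-gene z-scored
67%-interval widths (α = 0.33; the width plays the role of an asymmetric
standard error). Standardising widths by the per-gene *width* mean/sd is the
default; standardising by the per-gene *expression* mean/sd is available as
`standardize="expression"` for compatibility with the alternative reading of
the procedure. The removal threshold is Otsu's method on 256 equal-width
bins — the implementation evaluates the exact between-class variance of the
sample split at every interior bin edge and, because every edge inside one
inter-value gap ties exactly, returns the middle of the tied run; constant
scores yield a +∞ sentinel (nothing removed). With class labels the
threshold is computed per class, so classes with systematically different
prediction quality are not filtered against each other; singleton classes
are never filtered.

Weighted PCA inverts interval widths (floored at 1e−8 × the global mean
width), normalises per gene by the gene's mean, and either binarises at the
pooled 20th percentile into weights {1.0, 0.1} (ties get the high weight) or
takes log1p. The decomposition follows the weighted-covariance formulation:
C_jk = Σᵢ wᵢⱼwᵢₖ(xᵢⱼ−μⱼ)(xᵢₖ−μₖ) / Σᵢ wᵢⱼwᵢₖ with weighted per-gene means,
eigendecomposition of C, and per-cell weighted least squares (weights w²)
for the embedding; uniform weights reproduce standard PCA exactly, which the
tests assert. An all-zero-weight cell falls back to unweighted projection
with a warning.

The replicate-stability score centres each 2-D layout, rigidly aligns it
(rotation/reflection via orthogonal Procrustes, no scaling) to the first
layout on their shared cells, and scores each cell by the mean squared
deviation of its aligned positions from their centroid across the layouts
containing it, divided by the mean squared distance of reference positions
to their centroid. This is a reimplementation from a published description
of a dynamic-visualisation variance score, not a port of that tool; the
normalisation is therefore approximate, and its absolute scale should be
read with that caveat. Layouts for the stability experiment are plain PCA
(centering only) of the predicted matrix; the supervised/clustering
evaluation harness standardises features first, where that step is part of
the published pipeline (L1 logistic regression under stratified 5-fold CV;
k-means with k = n_classes and a linear SVC on the top 15 PCs).

## The synthetic data

The simulator emulates a reference-free ZINB spatial simulation: cells
uniform in the unit square, two groups split by a linear boundary (a rank
split along the boundary normal hits the exact design sizes: 465/515 for
the null differential-expression design, 476/504 for the two-cluster
design), counts ~ ZINB with zero proportion 0.05, NB mean 2 and dispersion
0.5. **Dispersion is the NB size parameter r** (variance = m + m²/r),
the convention of the R simulation ecosystem this design follows; if the
reciprocal convention were intended the counts would be markedly less
overdispersed. The two-cluster design doubles the NB mean of 500 signal
genes in group B. Prediction error is injected on the count scale: either
N(μ, 1) noise on a seeded half of the genes in group B and N(0, 1)
elsewhere (false-DE stress test), or mix-in bias — round(prop × n_A)
group-A cells have every gene replaced by a uniform draw from group-B truth
values, N(0, 1) noise added to all other entries. Negative "predicted"
values are allowed; predictions are not counts. Cells are emitted ordered
along the boundary normal so a given cell index belongs to the same group
in every seeded replicate, which is what makes cross-replicate alignment
meaningful.

What the simulator does not emulate: spatially smooth expression gradients,
cell-type hierarchies beyond two groups, gene-gene correlation, segmentation
artefacts, or realistic predictor error structure (errors here are iid
Gaussian or wholesale identity swaps). Passing tests on this data
demonstrate the statistical machinery — coverage, variance pooling,
threshold behaviour — not real-data imputation quality.

## Problem sizes and determinism

All stochastic steps take explicit seeds (numpy `default_rng`; imputation
ensembles derive one child seed per imputation from a `SeedSequence`, so
imputations are regenerated on demand instead of stored). The test suite
runs the full 980 × 1000 designs where an experiment's definition depends on
them (coverage, false-DE rates with D = 100 over 20 replicates per bias
level, filtering gains over 20 replicates, the 20-replicate stability
experiment) and small matrices everywhere the property under test is
size-free.

## Known limitations

* The baseline kNN-on-joint-PCA predictor deliberately omits any batch
  integration between spatial and dissociated data; it exists to make the
  wrapper hermetically testable and is not a substitute for purpose-built
  imputation methods on real data.
* Marginal (and group-marginal) coverage is guaranteed under gene
  exchangeability; per-gene conditional coverage is not, and genes with
  extremely sparse expression calibrate poorly.
* The stratification mapping for genes unseen at calibration assumes the
  deployment prediction covers the same cells as calibration; mapping new
  cells additionally requires the stratum's genes to be present.
* Otsu-based filtering always proposes a split; on unimodal score
  distributions it removes a substantial fraction of cells even when no
  high-uncertainty mode exists. This mirrors the described procedure but is
  worth checking via the returned thresholds before trusting a filtered
  analysis.
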