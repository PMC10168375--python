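# tissue

Calibrated uncertainty for predicted single-cell spatial gene expression.

Imaging-based spatial transcriptomics (MERFISH, seqFISH, osmFISH, ISS, ...)
measures a few hundred genes per cell; the rest of the transcriptome is
routinely *imputed* from a paired dissociated scRNA-seq reference. Those
imputations vary wildly in quality across cells, genes, datasets and
prediction methods — and they ship with no error bars, so downstream
differential-expression tests, classifiers, clusterings and embeddings built
on them silently inherit the prediction error.

`tissue` is a predictor-agnostic conformal-inference wrapper that attaches
well-calibrated, asymmetric prediction intervals to any spatial
gene-expression prediction, and uses them for uncertainty-aware downstream
analysis. It works with any imputation model through a one-function plug-in
contract, ships a simple kNN-on-joint-PCA baseline predictor, and includes a
zero-inflated negative binomial (ZINB) spatial simulator so the entire
framework can be exercised end to end without external data.

## The method

For cell *i* and gene *j* with prediction X̂*ᵢⱼ*, the **cell-centric
variability** aggregates disagreement with the spatial neighbourhood
*Nᵢ* (the K = 15 nearest cells, outlier edges pruned at Q3 + 1.5 IQR):

```
U_ij = 1 + Σ_{k∈N_i} W_ik (X̂_kj − X̂_ij)² / Σ_{k∈N_i} W_ik ,
W_ik = exp( cos(X̂_i,· , X̂_k,·) )
```

so deviation from transcriptionally similar neighbours (same cell type)
counts more than deviation from dissimilar ones. Cross-validated predictions
of the *measured* panel give calibration scores

```
s_ij = |X_ij − X̂_ij| / U_ij ,
```

split by the sign of the error into lower/upper sets (optionally stratified
into k_g gene × k_c cell groups by k-means on PCA embeddings, with a
fall-back to the pooled set for groups with < 100 scores per side). The
conformal quantile q_α = the ⌈(n+1)(1−α)⌉-th smallest score then yields the
asymmetric interval with ≥ 1−α marginal coverage:

```
I_ij = [ X̂_ij − U_ij·q_α⁽ˡ⁾ ,  X̂_ij + U_ij·q_α⁽ᵘ⁾ ].
```

On top of the intervals the package provides:

* **multiple-imputation hypothesis testing** — resample calibration scores
  to generate D plausible imputations, pool within/between-imputation
  variance (Rubin's rules are applied in the modified two-sample t-test, and
  a probit p-value combination covers arbitrary per-imputation tests such as
  rank-sum), drastically reducing false DE discoveries caused by biased
  predictions;
* **uncertainty-aware cell filtering** — per-class Otsu thresholding of
  mean z-scored 67%-interval widths, improving clustering, classification
  and visualisation;
* **weighted PCA** — inverse-interval-width weights (binary 10:1 or log
  scheme) in a Delchambre weighted-covariance decomposition.

## Worked example

Simulate the two-group null design (980 cells, 1000 genes, ZINB counts, no
true expression difference), corrupt it with group-selective prediction bias
(N(1, 1) noise on half the genes of group B only), calibrate, and test:

```python
import numpy as np
from tissue import *

sim = inject_de_bias(simulate_counts(de_design(seed=1)), bias_mu=1.0, seed=2)
pred = sim.predicted                      # truth + biased "prediction error"

_, _, U = variability_from_coords(pred, sim.truth.coords, K=15)
model = build_calibration(sim.truth, pred, U, k_g="auto", k_c="auto", seed=0)

iv = build_intervals(pred, U, model, alpha=0.33)
covered = np.mean((sim.truth.values >= iv.lower) & (sim.truth.values <= iv.upper))
print(f"67% interval coverage: {covered:.3f}")

ens = sample_imputations(pred, U, model, D=100, seed=3)
table = de_scan(ens, sim.group_array, mode="ttest", fdr=0.05)
print("MI false DE calls:", int(table[table.label == 'A'].significant.sum()))
```

prints

```
67% interval coverage: 0.670
MI false DE calls: 0
```

The 67% prediction intervals cover almost exactly 67% of the held measured
values, and the multiple-imputation t-test makes **0** false
differential-expression calls out of 1000 truly-null genes — the naive
per-gene t-test on the same biased predictions makes 516 (BH, FDR 5%): the
injected bias manufactures spurious group differences, and the imputation
ensemble's inflated variance absorbs them.

The same pipeline is scriptable from a shell (`tissue simulate`, `tissue
predict`, `tissue calibrate`, `tissue intervals`, `tissue coverage`,
`tissue test`, `tissue filter`, `tissue evaluate`); every subcommand takes
`--seed` and echoes its configuration next to its outputs.

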