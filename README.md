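# polyfate

Polynomial cell-fate prediction from single-cell gene expression.

Many diseases — type 2 diabetes (T2D) among them — involve the progressive
death of specific cells, and single-cell transcriptomes make that fate
readable: the executioner caspases (CASP3, CASP6, CASP7) carry out
apoptosis, so a cell's combined caspase expression is a direct readout of
how likely it is to die. `polyfate` turns that readout into a supervised
modeling pipeline for researchers who want to predict and interpret cell
death from expression data (pancreatic islet biology is the motivating
setting, but nothing is pancreas-specific):

1. **Labeling.** Each cell's death probability is
   `P = (CASP3 + CASP6 + CASP7) / max over cells of that sum`, with
   `P >= 0.5` classing the cell as likely to die.
2. **Feature selection.** Predictor genes are chosen either by the
   absolute Spearman rank correlation `ρ = cov(X_R, Y_R) / (σ_X_R σ_Y_R)`
   between each gene and `P` (data-driven), or as a fixed 32-gene
   apoptosis-pathway panel with cross terms for known regulatory pairs
   such as TP53×MDM2 (knowledge-driven).
3. **Model.** `P` is approximated by a truncated polynomial in the
   log2(RPKM + 1) expression levels `x_1 … x_l`:

   `P = b + Σ_{p=1..n} Σ_{m=1..l} k_mp · x_m^p + Σ_{(i,j)} k'_ij · x_i x_j`

   fitted by ordinary least squares; with `l` genes, degree `n` and `M`
   cross-term pairs the model has `1 + l·n + M` parameters.
4. **Evaluation.** Repeated 10×10-fold cross-validation (100 refits),
   with genes re-selected inside every training fold; a prediction is
   correct when predicted and actual `P` share an interval
   (`[0, 0.5)` or `[0.5, 1]`).
5. **Stability.** Across the 100 refits: per-coefficient min–max ranges,
   and the variance of the 100 predictions at each of 10,000 randomly
   sampled expression points. The mean of those variances (**MVAV**)
   is a single instability score — smaller is more stable. The variance
   distribution is summarised by a maximum-likelihood gamma fit.

A seeded synthetic-data generator reproduces the assumed data structure
(skewed RPKM-like expression, caspase markers encoding a latent `P`,
informative vs noise genes, two donor groups), so every stage is testable
with a known ground truth.

## Worked example

```python
import polyfate as pf

data = pf.simulate_dataset(pf.SimulationConfig(seed=5))        # 2000 cells
labels = pf.compute_death_probability(data.matrix)             # P per cell
predictors = pf.ensure_log(pf.exclude_marker_genes(data.matrix))

fs = pf.FeatureSet(genes=list(data.informative_genes), mode="pathway")
points = pf.sample_stability_points(predictors, fs.genes, 10_000, seed=5)
for degree in (1, 3):
    cv = pf.run_repeated_cv(predictors, labels,
                            pf.CVConfig(degree=degree, mode="pathway",
                                        pathway_features=fs, seed=5))
    mvav = pf.stability_report(cv.models, points).mvav
    print(degree, round(cv.mean_accuracy, 4), f"{mvav:.3e}")
```

prints

```
1 0.9492 9.077e-07
3 0.9482 8.842e-06
```

— the linear and cubic models are nearly tied on interval accuracy
(0.9492 vs 0.9482), but the linear model's MVAV is an order of magnitude
smaller: it predicts just as well while being far more stable under
resampling of the training cells, which is the pipeline's central
comparison. The `examples/` directory walks through each capability
(labeling, selection, fitting, CV, stability, group comparison, the full
grid) as short narrative scripts; a thin `polyfate` CLI mirrors the same
stages (`polyfate --help`).

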