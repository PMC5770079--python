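# Methods

## Model

The quantity modeled is a per-cell death probability `P ∈ [0, 1]`. The
rationale is that any smooth relationship between expression levels and
fate admits a power-series expansion, so a finite polynomial is a
principled family of approximations whose complexity is a single knob
(the degree). With predictor genes `x_1 … x_l` (their log-scale
expression) the degree-`n` model with cross terms is

    P = b + Σ_{p=1..n} Σ_{m=1..l} k_mp x_m^p + Σ_{(i,j)} k'_ij x_i x_j

Per-gene power terms assume gene effects are additive; a product term
`x_i x_j` is added for each configured pair of regulatorily related
genes to capture the leading non-additive (synergistic) effect. Higher
mixed powers `x_i^p x_j^q` (p or q > 1) and three-way interactions are
deliberately out of scope: one product per pair is what keeps the
parameter count at `1 + l·n + M` (33/65/97 for 32 genes at degrees 1–3;
71 for degree 2 with six pairs), and that count is itself a documented
property of the model family. Degrees are restricted to 1–3; beyond
that, collinearity between powers of skewed expression values makes OLS
fits uninterpretable long before they become useful.

Coefficients are estimated by ordinary least squares (no regularisation
— instability is *measured*, not penalised away) via a rank-revealing
SVD solver. A rank-deficient design yields the minimum-norm solution
with a warning rather than an error, because per-fold refits on small
gene panels can transiently lose rank without invalidating the run.
Predictions are not clipped to [0, 1]: classification applies the 0.5
threshold, which clipping cannot change.

## Labeling

`P = combined / max(combined)` where `combined` is the raw-scale sum of
CASP3 + CASP6 + CASP7 per cell and the max runs over exactly the cells
supplied. Consequences worth knowing: the arg-max cell always has
`P = 1`; labels are invariant to a common rescaling of the markers; and
removing the max cell rescales everyone. The boundary `P = 0.5` belongs
to the "high" (likely-to-die) class — the decision intervals are
`[0, 0.5)` and `[0.5, 1]`. Marker summation uses the raw scale because
the readout is the combined expression level itself; a log-scale option
exists but is off by default.

## Scales

Expression arrives as non-negative RPKM-like values. Modeling operates
on `log2(x + 1)` (configurable): RPKM is heavily right-skewed and the
log makes the polynomial's low-order terms do the work. Labeling and
donor-group comparisons default to the raw scale, since both interpret
expression levels directly. Both choices are flags on the corresponding
functions.

## Feature selection

Correlation mode ranks genes by `|ρ|`, the absolute Spearman rank
correlation with `P` (average ranks for ties; Pearson on the ranks).
Selection happens *inside every training fold* — the test fold
never influences which genes are chosen; this is asserted by a
perturbation test. Ties in `|ρ|` break by input gene order so a run is
reproducible. A constant gene gets `ρ = 0` in the vectorised ranking
(nothing monotone to measure), while the scalar `spearman_rho` on a
constant vector raises, because there the caller asked for a number
that does not exist. Cross-term pairs in correlation mode are the
most inter-correlated gene pairs among the selected genes, ranked by
`|ρ|` between the two genes' profiles.

Pathway mode uses a fixed 32-gene apoptosis panel (APAF1 … XIAP) in
every fold, with six regulatory cross-term pairs. Only TP53–MDM2 is
fixed by the pathway description; the other five — TP53–BAX, TP53–BCL2,
TP53–FAS, ATF4–DDIT3, DDIT3–BCL2 — are this repository's choice of
standard transcription-regulation relationships among the listed genes,
and the pair list is a plain configuration input for anyone who
disagrees.

## Cross-validation and accuracy

10 folds × 10 repeats by default: each repeat draws a fresh random
near-equal partition (sizes differ by at most one), giving 100 fitted
functions and 100 test accuracies whose mean is the reported estimate.
Repeat `r` seeds its partition with `seed + r`, so any single repeat can
be replayed in isolation. No stratification — the partition is plain
random. Interval accuracy is the fraction of test cells whose predicted
and actual `P` land on the same side of 0.5; out-of-range predictions
classify by the same threshold.

## Stability and MVAV

Stability asks how much the fitted function moves when the training set
changes, using the 100 CV refits as the resampling ensemble:

* **Parameter ranges** — min/max/width per coefficient position, with
  positions aligned as intercept, then each power block with genes in
  importance order, then cross terms. In correlation mode different
  refits may select different genes; aligning by importance rank is the
  interpretation adopted here (position `i` means "the i-th most
  death-correlated gene of that refit"), and the same rank-based mapping
  feeds the point predictions below.
* **Point variances and MVAV** — `n_points` (default 10,000) points are
  drawn once per gene count, each coordinate independently uniform over
  that gene's observed log-scale [min, max]; every refit is evaluated at
  every point and the per-point sample variance (n−1 denominator) is
  taken. MVAV is the mean of those variances. Uniform-in-observed-range
  is the least-assumption sampling choice (an empirical-resampling
  alternative is noted in the code); the denominator and the sampling
  law are both conventions, so MVAVs are comparable only within a fixed
  point set — which is why the pipeline reuses one point set across all
  models with the same gene count, and why identical refits give an
  exactly zero MVAV (variances are computed shift-invariantly).
* **Variance distribution** — a maximum-likelihood gamma fit (location
  fixed at 0, zeros excluded and counted) with a one-sample
  Kolmogorov–Smirnov check at α = 0.05, plus empirical PDF/CDF tables.
  Fitting and testing on the same sample is anti-conservative; the
  p-value is reported as-is rather than corrected, since the fit is a
  descriptive summary, not an inference.

## Group comparison

Student's pooled-variance two-sample t-test (df = n_a + n_b − 2),
two-sided, with a Welch option; significance at p < 0.05 and no
multiple-testing correction (the comparison covers three markers plus
their sum — a fixed, tiny family). The extent of difference is
`1 − mean_A/mean_B` with group B the disease reference, positive when
the disease group expresses more.

## Synthetic data

The generator emulates the data structure the pipeline assumes, with
defaults fixed at the reference study conditions: 2,000 cells, 200 genes
(three of them markers), 10 informative genes, label noise SD 0.02,
marker scale 100 (an RPKM-like combined-caspase ceiling), donor groups
at a 40% disease fraction with no shift unless requested. Expression
marginals are log-normal on the raw scale (gene-specific location
uniform on [0, 3] in natural-log units, shape 1) — the canonical
skew of RPKM data. The latent `P` is a polynomial (degree 1 or 2) in
the log-scale informative genes with random ±[0.3, 1] weights, affinely
rescaled onto [0.05, 1.0]; the rescale keeps the generating model
exactly polynomial (so noiseless fits must recover the echoed realized
coefficients to machine precision), pins the dataset maximum at 1 (so
max-normalised labeling returns `P` itself), and leaves clipping to
[0, 1] active only on noise excursions. Gaussian label noise and the
optional additive disease-group shift are applied before clipping. The
markers' raw-scale sum equals `P × marker_scale` exactly, split across
CASP3/6/7 by a symmetric Dirichlet(5,5,5) draw — individual markers are
noisy, their sum is not.

What the generator does *not* emulate: scRNA-seq count noise (dropout,
library-size variation), cell-type structure, gene–gene co-expression
beyond what the shared latent `P` induces, and donor-level batch
effects. Passing tests therefore certify the pipeline's statistical
machinery — labeling algebra, selection without leakage, OLS recovery,
CV bookkeeping, the MVAV ordering between model degrees — not
performance on real tissue.

## Numerical choices and edge cases

* Rank decisions in OLS use numpy's machine-epsilon-scaled singular
  value cutoff (`rcond=None`).
* Fold sizes come from an `array_split` of a seeded permutation: sizes
  differ by at most one, deterministically.
* A constant gene in the stability point sampler collapses that
  dimension to the constant, with a warning.
* Degenerate labels (all marker sums zero) and constant labels in a
  training fold raise dedicated errors rather than propagating NaNs.
* Grid cells asking for more gene pairs than `C(k, 2)` are reported as
  "not applicable" (`-` in the TSV tables), not silently skipped.

## Problem sizes in the checked experiments

The recovery and stability-ordering experiments in the test suite run at
the generator's reference conditions (2,000 cells, 10 informative genes,
five seeds, 10×10 CV, 10,000 stability points). The orchestration and
unit tests use smaller draws (hundreds of cells, ≤ 100 genes) — these
sizes are the package's own choice of the smallest instances that still
exercise every code path with meaningful statistics.

## Known limitations

* Accuracy near the information bound: label noise at the 0.5 boundary
  caps achievable interval accuracy; with the default bell-shaped latent
  `P`, roughly 4–5% of cells are within noise distance of the
  threshold.
* The rank-based gene alignment across correlation-mode refits is an
  interpretation; when refits select very different genes, "the i-th
  ranked gene" may not be biologically the same gene across refits.
* The KS gamma check is descriptive (see above) and will reject for
  large samples even at visually excellent fits.
* No uncertainty quantification on coefficients (by design — stability
  is measured by resampling instead).
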