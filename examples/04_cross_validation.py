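"""Score the model by repeated 10-fold cross-validation.

Ten random 10-fold partitions yield 100 train/test splits; genes are
re-selected inside every training fold so the test cells never leak into
selection.  A prediction counts as correct when predicted and actual P
fall in the same interval, [0, 0.5) or [0.5, 1].
"""

import polyfate as pf

data = pf.simulate_dataset(pf.SimulationConfig(seed=4))
labels = pf.compute_death_probability(data.matrix)
predictors = pf.ensure_log(pf.exclude_marker_genes(data.matrix))

for degree in (1, 2, 3):
    cv = pf.run_repeated_cv(
        predictors, labels,
        pf.CVConfig(degree=degree, mode="correlation", top_k=10, seed=0),
    )
    print(f"degree {degree}: mean interval accuracy "
          f"{cv.mean_accuracy:.4f} over {cv.n_models} models "
          f"(fold std {cv.accuracies.std():.4f})")
print("accuracies barely differ across degrees: on near-linear data every "
      "truncation predicts the 0.5 interval about equally well.")
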