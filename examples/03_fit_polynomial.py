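"""Fit the polynomial cell-fate model and recover known coefficients.

With noiseless synthetic data generated by a linear rule, ordinary least
squares on the log-scale design matrix returns the generating coefficients
to machine precision; the design-matrix column count is 1 + l*degree + M.
"""

import numpy as np

import polyfate as pf

data = pf.simulate_dataset(
    pf.SimulationConfig(n_cells=400, n_genes=40, n_informative=5,
                        noise_sd=0.0, seed=3)
)
labels = pf.compute_death_probability(data.matrix)
predictors = pf.ensure_log(pf.exclude_marker_genes(data.matrix))

spec = pf.PolynomialSpec(degree=1, genes=tuple(data.informative_genes))
fitted = pf.fit_model(predictors, labels.p_death, spec)

print(f"model parameters: {spec.n_params} "
      f"(intercept + {len(spec.genes)} genes x degree {spec.degree})")
print(f"{'term':10s} {'true':>9s} {'fitted':>9s}")
for name, true, est in zip(spec.term_names(), data.realized_coefficients,
                           fitted.coefficients):
    print(f"{name:10s} {true:9.4f} {est:9.4f}")
err = np.abs(fitted.coefficients - data.realized_coefficients).max()
print(f"max coefficient error: {err:.2e} (noiseless data is interpolated exactly)")

# the 32-gene apoptosis-pathway model sizes
for degree, pairs in [(1, ()), (2, ()), (3, ()), (2, pf.DEFAULT_REGULATORY_PAIRS)]:
    s = pf.PolynomialSpec(degree, pf.APOPTOSIS_GENES, pairs)
    extra = f" + {len(pairs)} cross terms" if pairs else ""
    print(f"32 pathway genes, degree {degree}{extra}: {s.n_params} parameters")
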