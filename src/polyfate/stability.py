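"""Stability of the fitted polynomials across cross-validation refits.

A model retrained on 100 slightly different training sets yields 100
coefficient vectors and 100 prediction functions.  Two complementary views
quantify how much they disagree:

* **Parameter ranges** — the min-max envelope of every coefficient
  position across refits (intercept first, then power-term coefficients
  with genes in importance order within each power block, then cross
  terms).  Narrow envelopes mean the regression is insensitive to which
  cells happened to land in the training set.
* **Prediction variance at sampled points** — draw a fixed set of points
  in expression space (each coordinate uniform within the corresponding
  gene's observed range), evaluate every refit at every point, and take
  the per-point sample variance.  The mean of those variances (MVAV) is a
  single instability number: smaller MVAV, more stable model.  The same
  point set must be reused when comparing models over the same gene count,
  and the point-variance distribution is summarised by a maximum-likelihood
  gamma fit with a goodness-of-fit check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

from .errors import ParameterError
from .io import ExpressionMatrix
from .model import FittedModel, predict_points


@dataclass(frozen=True)
class GammaFit:
    """MLE gamma fit to the point-variance distribution."""

    shape: float
    scale: float
    p_value: float
    passed: bool
    n_used: int
    n_zero: int
    pdf_table: np.ndarray  # columns: bin centre, empirical density, fitted density
    cdf_table: np.ndarray  # columns: value, empirical CDF, fitted CDF


@dataclass
class StabilityReport:
    """Per-parameter ranges, per-point variances, MVAV and gamma summary."""

    param_ranges: np.ndarray  # (n_params, 3): min, max, width
    point_variances: np.ndarray
    mvav: float
    gamma_fit: GammaFit | None
    n_models: int

    def to_dict(self) -> dict:
        g = self.gamma_fit
        return {
            "n_models": self.n_models,
            "mvav": self.mvav,
            "param_ranges": self.param_ranges.tolist(),
            "gamma_fit": None
            if g is None
            else {
                "shape": g.shape,
                "scale": g.scale,
                "p_value": g.p_value,
                "passed": g.passed,
                "n_used": g.n_used,
                "n_zero": g.n_zero,
            },
        }


def sample_stability_points(
    m: ExpressionMatrix,
    genes: Sequence[str],
    n_points: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Sample points in expression space for variance probing.

    Each dimension i is drawn independently and uniformly within gene i's
    observed [min, max] across the cells of ``m`` (on whatever scale ``m``
    carries — use the modeling scale).  Deterministic given the seed; a
    constant gene collapses its dimension to that constant with a warning.
    The same point set should be reused for every model with the same gene
    count so MVAVs are comparable.
    """
    if n_points < 1:
        raise ParameterError("n_points must be positive")
    cols = m.values[:, [m.gene_index(g) for g in genes]]
    lo, hi = cols.min(axis=0), cols.max(axis=0)
    flat = np.flatnonzero(hi == lo)
    if flat.size:
        warnings.warn(
            f"constant gene dimension(s) {[genes[i] for i in flat]}; "
            "sampled at the constant value"
        )
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=(n_points, len(genes)))


def point_prediction_variances(
    models: Sequence[FittedModel], points: np.ndarray
) -> np.ndarray:
    """Sample variance (n-1 denominator) of the refits' predictions per point.

    Point dimension i feeds the i-th ranked gene of each model's spec, so
    correlation-mode refits that selected different genes are aligned by
    importance rank, mirroring the rank-based alignment of the parameter
    ranges.
    """
    if len(models) < 2:
        raise ParameterError("need at least 2 models for a variance")
    n_genes = len(models[0].spec.genes)
    for mod in models:
        if len(mod.spec.genes) != n_genes:
            raise ParameterError("all models must share the same gene count")
    preds = np.stack([predict_points(mod, points) for mod in models])
    # shift by the first model's predictions so identical refits give an
    # exact zero instead of accumulated rounding in the mean
    return (preds - preds[0]).var(axis=0, ddof=1)


def compute_mvav(variances: Sequence[float]) -> float:
    """Mean value of all the variances — the scalar instability measure."""
    v = np.asarray(variances, dtype=float)
    if v.size == 0:
        raise ParameterError("empty variance vector")
    if (v < 0).any():
        raise ValueError("variances must be non-negative")
    return float(v.mean())


def parameter_range_report(models: Sequence[FittedModel]) -> np.ndarray:
    """(min, max, width) of each coefficient position across refits.

    Positions follow the design-column order: intercept, then each power
    block with genes in importance order, then cross terms.  All models
    must have the same parameter count.
    """
    if len(models) < 2:
        raise ParameterError("need at least 2 models for a range")
    n = models[0].n_params
    for mod in models:
        if mod.n_params != n:
            raise ParameterError("models have mismatched parameter counts")
    coefs = np.stack([mod.coefficients for mod in models])
    lo, hi = coefs.min(axis=0), coefs.max(axis=0)
    return np.column_stack([lo, hi, hi - lo])


def fit_variance_distribution(
    variances: Sequence[float], alpha: float = 0.05, n_bins: int = 50
) -> GammaFit:
    """MLE gamma fit to the positive point variances plus a KS check.

    Zero variances are excluded (their count is reported); fewer than 50
    positive entries is considered insufficient.  The pass flag records
    whether a one-sample Kolmogorov-Smirnov test against the fitted gamma
    retains the distribution at level ``alpha``.  Fitting and testing on
    the same sample makes the test anti-conservative; the p-value is
    reported as-is.
    """
    v = np.asarray(variances, dtype=float)
    if (v < 0).any():
        raise ValueError("variances must be non-negative")
    pos = v[v > 0]
    n_zero = int(v.size - pos.size)
    if pos.size < 50:
        raise ParameterError(
            f"only {pos.size} positive variances; need at least 50"
        )
    shape, _, scale = scipy.stats.gamma.fit(pos, floc=0.0)
    ks = scipy.stats.kstest(pos, "gamma", args=(shape, 0.0, scale))
    dist = scipy.stats.gamma(shape, scale=scale)

    counts, edges = np.histogram(pos, bins=n_bins, density=True)
    centres = 0.5 * (edges[:-1] + edges[1:])
    pdf_table = np.column_stack([centres, counts, dist.pdf(centres)])
    xs = np.sort(pos)
    ecdf = np.arange(1, xs.size + 1) / xs.size
    cdf_table = np.column_stack([xs, ecdf, dist.cdf(xs)])

    return GammaFit(
        shape=float(shape),
        scale=float(scale),
        p_value=float(ks.pvalue),
        passed=bool(ks.pvalue >= alpha),
        n_used=int(pos.size),
        n_zero=n_zero,
        pdf_table=pdf_table,
        cdf_table=cdf_table,
    )


def stability_report(
    models: Sequence[FittedModel],
    points: np.ndarray,
    alpha: float = 0.05,
) -> StabilityReport:
    """Full stability summary for a family of refits at a shared point set."""
    variances = point_prediction_variances(models, points)
    try:
        gamma = fit_variance_distribution(variances, alpha=alpha)
    except ParameterError:
        gamma = None
    return StabilityReport(
        param_ranges=parameter_range_report(models),
        point_variances=variances,
        mvav=compute_mvav(variances),
        gamma_fit=gamma,
        n_models=len(models),
    )
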