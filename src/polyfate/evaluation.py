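"""Repeated 10-fold cross-validation with interval-agreement accuracy.

Cells are randomly partitioned into ``n_folds`` near-equal folds; each fold
serves once as the test set while the remaining cells train the model.
Feature selection (correlation mode) is redone inside every training fold,
so the test cells never influence which genes are selected.  Repeating the
whole partition ``n_repeats`` times with fresh randomness yields
``n_folds * n_repeats`` fitted prediction functions — 100 for the default
10 x 10 setting — whose accuracies are averaged into a single estimate.

A prediction counts as correct when the predicted and actual death
probabilities fall in the same decision interval, [0, 0.5) or [0.5, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ParameterError
from .features import (
    FeatureSet,
    pathway_feature_set,
    rank_gene_pairs,
    select_top_correlated,
)
from .io import ExpressionMatrix, ensure_log
from .labeling import DEATH_THRESHOLD, FateLabels
from .model import FittedModel, PolynomialSpec, fit_model, predict


@dataclass
class CVConfig:
    """Settings for one repeated cross-validation run."""

    degree: int = 1
    mode: Literal["correlation", "pathway"] = "correlation"
    top_k: int = 10
    n_pairs: int = 0
    pathway_features: FeatureSet | None = None
    n_folds: int = 10
    n_repeats: int = 10
    seed: int = 0
    log_predictors: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ParameterError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ParameterError("n_repeats must be >= 1")


@dataclass
class CVResult:
    """All per-fold accuracies, fitted models and selected feature sets."""

    config: CVConfig
    accuracies: np.ndarray  # shape (n_repeats, n_folds)
    models: list[FittedModel]
    feature_sets: list[FeatureSet]
    fold_assignments: list[list[np.ndarray]] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def n_models(self) -> int:
        return len(self.models)


def make_folds(n_cells: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Random partition of cell indices into near-equal disjoint folds.

    Fold sizes differ by at most one (2209 cells in 10 folds gives nine of
    221 and one of 220); the partition is deterministic given the seed.
    """
    if n_folds > n_cells:
        raise ParameterError(f"n_folds={n_folds} exceeds n_cells={n_cells}")
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_cells)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def interval_accuracy(
    predicted: Sequence[float], actual: Sequence[float]
) -> float:
    """Fraction of cells whose predicted and actual P share an interval.

    The intervals are [0, 0.5) and [0.5, 1]; predictions outside [0, 1]
    classify by the same 0.5 threshold.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.ndim != 1 or predicted.size == 0:
        raise ParameterError("predicted and actual must be equal-length, non-empty")
    return float(
        np.mean((predicted >= DEATH_THRESHOLD) == (actual >= DEATH_THRESHOLD))
    )


def _select_features(
    train: ExpressionMatrix, train_labels: FateLabels, cfg: CVConfig
) -> FeatureSet:
    if cfg.mode == "pathway":
        fs = cfg.pathway_features or pathway_feature_set()
        return fs
    fs = select_top_correlated(train, train_labels, cfg.top_k)
    if cfg.n_pairs > 0:
        fs = rank_gene_pairs(train, fs, cfg.n_pairs)
    return fs


def run_repeated_cv(
    m: ExpressionMatrix, labels: FateLabels, cfg: CVConfig
) -> CVResult:
    """Run the full repeated-CV protocol and collect every fitted model.

    ``m`` must already exclude the labeling marker genes.  Predictors are
    log2(x+1)-transformed unless ``cfg.log_predictors`` is off or the
    matrix is already log scale.  Repeat r draws its folds from sub-seed
    ``seed + r`` so individual repeats can be audited in isolation.
    """
    if m.n_cells != len(labels):
        raise ParameterError("matrix and labels disagree on cell count")
    x = ensure_log(m) if cfg.log_predictors else m
    acc = np.empty((cfg.n_repeats, cfg.n_folds))
    models: list[FittedModel] = []
    feature_sets: list[FeatureSet] = []
    assignments: list[list[np.ndarray]] = []
    for r in range(cfg.n_repeats):
        folds = make_folds(x.n_cells, cfg.n_folds, cfg.seed + r)
        assignments.append(folds)
        for f, test_idx in enumerate(folds):
            mask = np.ones(x.n_cells, dtype=bool)
            mask[test_idx] = False
            train_idx = np.flatnonzero(mask)
            train = x.subset_cells(train_idx)
            train_labels = labels.subset(train_idx)
            fs = _select_features(train, train_labels, cfg)
            spec = PolynomialSpec(cfg.degree, tuple(fs.genes),
                                  tuple(fs.cross_pairs))
            fitted = fit_model(train, train_labels.p_death, spec)
            test = x.subset_cells(test_idx)
            pred = predict(fitted, test)
            acc[r, f] = interval_accuracy(pred, labels.p_death[test_idx])
            models.append(fitted)
            feature_sets.append(fs)
    return CVResult(cfg, acc, models, feature_sets, assignments)
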