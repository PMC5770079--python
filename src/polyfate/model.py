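"""The truncated polynomial cell-fate model and its least-squares fit.

The death probability P of a cell is modeled as a finite polynomial in the
expression levels x_1..x_l of the selected genes,

    P = b + sum_{p=1..n} sum_{m=1..l} k_{mp} x_m^p + sum_{(i,j)} k'_{ij} x_i x_j,

i.e. per-gene power terms up to the chosen degree n plus, optionally, one
product cross term per configured gene pair to capture synergy between
regulatorily related genes.  With l genes, degree n and M pairs the model
has 1 + l*n + M free parameters (so the 32-gene pathway model has 33, 65
and 97 parameters at degrees 1-3, and 71 at degree 2 with six pairs).

Coefficients are estimated by ordinary least squares on a design matrix
whose columns are ordered: intercept, then for each power p = 1..n the
genes in importance order raised to p, then the cross products in pair
order.  The solver is numpy's rank-revealing SVD least squares; a
rank-deficient design yields the minimum-norm solution with a warning
rather than an error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .io import ExpressionMatrix


@dataclass(frozen=True)
class PolynomialSpec:
    """Degree, ordered predictor genes and cross-term pairs.

    Fully determines the design matrix; ``degree`` is the truncation order
    of the per-gene power series and is restricted to 1..3 here.
    """

    degree: int
    genes: tuple[str, ...]
    cross_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(
            self, "cross_pairs", tuple(tuple(p) for p in self.cross_pairs)
        )
        if self.degree not in (1, 2, 3):
            raise ParameterError(f"degree must be 1, 2 or 3, got {self.degree}")
        if not self.genes:
            raise ParameterError("spec needs at least one gene")
        gene_set = set(self.genes)
        for a, b in self.cross_pairs:
            if a not in gene_set or b not in gene_set:
                raise ParameterError(f"cross pair ({a}, {b}) not in spec genes")

    @property
    def n_params(self) -> int:
        """1 (intercept) + l * degree + number of cross terms."""
        return 1 + len(self.genes) * self.degree + len(self.cross_pairs)

    def term_names(self) -> list[str]:
        names = ["intercept"]
        for p in range(1, self.degree + 1):
            names += [g if p == 1 else f"{g}^{p}" for g in self.genes]
        names += [f"{a}*{b}" for a, b in self.cross_pairs]
        return names


@dataclass
class FittedModel:
    """OLS coefficients bound to a :class:`PolynomialSpec`.

    Coefficient order matches the design columns: intercept b first, then
    the k_{mp} power coefficients, then the k'_{ij} cross coefficients.
    """

    spec: PolynomialSpec
    coefficients: np.ndarray
    rank: int | None = None
    residual_sumsq: float | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.spec is not None and len(self.coefficients) != self.spec.n_params:
            raise ParameterError(
                f"{len(self.coefficients)} coefficients for "
                f"{self.spec.n_params}-parameter spec"
            )

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def to_dict(self) -> dict:
        return {
            "spec": {
                "degree": self.spec.degree,
                "genes": list(self.spec.genes),
                "cross_pairs": [list(p) for p in self.spec.cross_pairs],
            },
            "coefficients": self.coefficients.tolist(),
            "rank": self.rank,
            "residual_sumsq": self.residual_sumsq,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        spec = PolynomialSpec(
            d["spec"]["degree"],
            tuple(d["spec"]["genes"]),
            tuple(tuple(p) for p in d["spec"]["cross_pairs"]),
        )
        return cls(spec, np.asarray(d["coefficients"]),
                   d.get("rank"), d.get("residual_sumsq"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def design_from_array(x: np.ndarray, spec: PolynomialSpec) -> np.ndarray:
    """Design matrix from an (n_points, l) array already in spec gene order."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(spec.genes):
        raise ParameterError(
            f"point array must be (n, {len(spec.genes)}), got {x.shape}"
        )
    gene_pos = {g: i for i, g in enumerate(spec.genes)}
    cols = [np.ones(x.shape[0])]
    for p in range(1, spec.degree + 1):
        cols.append(x if p == 1 else x**p)
    cross = [
        (x[:, gene_pos[a]] * x[:, gene_pos[b]])[:, None]
        for a, b in spec.cross_pairs
    ]
    return np.column_stack(cols + cross) if cross else np.column_stack(cols)


def build_design_matrix(m: ExpressionMatrix, spec: PolynomialSpec) -> np.ndarray:
    """Design matrix for the cells of ``m`` under ``spec``.

    Column order: intercept, genes^1 in spec order, genes^2, ..., then the
    cross products; raises on genes absent from the matrix.
    """
    x = m.values[:, [m.gene_index(g) for g in spec.genes]]
    return design_from_array(x, spec)


def fit_least_squares(
    design: np.ndarray,
    p: Sequence[float],
    spec: PolynomialSpec | None = None,
) -> FittedModel:
    """Ordinary least squares fit of the death probability.

    With full column rank the solution is the unique minimiser of the
    residual sum of squares (it satisfies the normal equations); otherwise
    the minimum-norm solution is returned with a rank warning.  Fewer rows
    than columns draws an under-determined warning.
    """
    design = np.asarray(design, dtype=float)
    p = np.asarray(p, dtype=float)
    if design.ndim != 2 or design.shape[0] != p.shape[0]:
        raise ParameterError(
            f"design rows ({design.shape[0]}) must match response length "
            f"({p.shape[0]})"
        )
    if design.shape[0] < design.shape[1]:
        warnings.warn(
            f"under-determined system: {design.shape[0]} rows < "
            f"{design.shape[1]} columns"
        )
    coef, rss, rank, _ = np.linalg.lstsq(design, p, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {design.shape[1]}); "
            "returning the minimum-norm solution"
        )
    resid = design @ coef - p
    return FittedModel(spec, coef, int(rank), float(resid @ resid))


def fit_model(m: ExpressionMatrix, p: Sequence[float], spec: PolynomialSpec) -> FittedModel:
    """Convenience: build the design from ``m`` and fit in one call."""
    return fit_least_squares(build_design_matrix(m, spec), p, spec)


def predict(model: FittedModel, m: ExpressionMatrix) -> np.ndarray:
    """Evaluate the fitted polynomial on the cells of ``m``.

    Predictions are not clipped to [0, 1]; downstream classification uses
    the 0.5 threshold, which is unaffected by out-of-range values.
    """
    return build_design_matrix(m, model.spec) @ model.coefficients


def predict_points(model: FittedModel, points: np.ndarray) -> np.ndarray:
    """Evaluate the polynomial at raw points in spec gene order."""
    return design_from_array(points, model.spec) @ model.coefficients
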