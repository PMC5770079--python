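"""Death-probability labels from executioner-caspase expression.

Caspases 3, 6 and 7 are the executioner proteases of apoptosis, so their
combined expression in a cell is taken as the readout of how likely the
cell is to die.  The per-cell death probability P is the combined marker
expression divided by the maximum combined value over all cells, giving
P in [0, 1] with the arg-max cell at exactly 1.  Cells with P >= 0.5 are
classed as likely to die ("high"), the rest as "low".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateLabelsError, MissingGeneError
from .io import ExpressionMatrix

#: Default marker identifiers (HGNC symbols of executioner caspases).
DEFAULT_MARKERS = ("CASP3", "CASP6", "CASP7")

#: Probability at or above which a cell is classed as likely to die.
DEATH_THRESHOLD = 0.5


@dataclass(frozen=True)
class FateLabels:
    """Per-cell death probability and the derived binary fate class."""

    cell_ids: list[str]
    p_death: np.ndarray
    fate_class: np.ndarray  # "low" / "high"

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_death", np.asarray(self.p_death, dtype=float))
        object.__setattr__(self, "fate_class", np.asarray(self.fate_class))
        if self.p_death.min() < 0 or self.p_death.max() > 1:
            raise ValueError("death probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.cell_ids)

    def subset(self, index) -> "FateLabels":
        index = np.asarray(index)
        return FateLabels(
            [self.cell_ids[i] for i in index],
            self.p_death[index],
            self.fate_class[index],
        )


def classify(p: np.ndarray) -> np.ndarray:
    """Binary fate class at the 0.5 threshold; 0.5 itself is "high"."""
    return np.where(np.asarray(p, dtype=float) >= DEATH_THRESHOLD, "high", "low")


def compute_death_probability(
    m: ExpressionMatrix, marker_genes: Sequence[str] = DEFAULT_MARKERS
) -> FateLabels:
    """Label every cell with P = combined marker expression / dataset max.

    The combined level is the plain sum of the marker genes' values, taken
    on whatever scale ``m`` carries (raw by default, matching the direct
    use of combined RPKM as the death readout).  The maximum is taken over
    exactly the cells present in ``m``.
    """
    missing = [g for g in marker_genes if g not in m.gene_ids]
    if missing:
        raise MissingGeneError(f"marker genes absent from matrix: {missing}")
    combined = m.values[:, [m.gene_index(g) for g in marker_genes]].sum(axis=1)
    peak = combined.max()
    if peak <= 0:
        raise DegenerateLabelsError(
            "all combined marker values are zero; death probability undefined"
        )
    p = combined / peak
    return FateLabels(list(m.cell_ids), p, classify(p))


def exclude_marker_genes(
    m: ExpressionMatrix, marker_genes: Sequence[str] = DEFAULT_MARKERS
) -> ExpressionMatrix:
    """Drop the marker columns so they cannot serve as predictors.

    Markers absent from the matrix are ignored with a warning; with the
    three default markers present, a 26,179-gene matrix yields 26,176
    candidate predictor genes.
    """
    present = [g for g in marker_genes if g in m.gene_ids]
    absent = [g for g in marker_genes if g not in m.gene_ids]
    if absent:
        warnings.warn(f"markers not in matrix, nothing to exclude: {absent}")
    if not present:
        return m
    keep = [g for g in m.gene_ids if g not in set(present)]
    return m.subset_genes(keep)
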