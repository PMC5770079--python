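"""Donor-group comparison of marker expression.

Healthy versus disease (e.g. T2D) comparisons of caspase expression use
the classic Student two-sample t-test (pooled variance, two-sided) and an
"extent of difference" statistic 1 - mean_healthy / mean_disease, which is
positive when the disease group expresses more of the marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

from .errors import ParameterError
from .io import ExpressionMatrix
from .labeling import DEFAULT_MARKERS

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """t-test and extent-of-difference summary for one gene (or combined)."""

    label: str
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    significant: bool
    extent: float


def two_sample_t_test(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Student's two-sample t statistic and two-sided p-value.

    Pooled variance with df = n_a + n_b - 2 by default; ``equal_var=False``
    switches to the Welch correction.  Two identical constant groups give
    t = 0, p = 1 rather than a 0/0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 observations")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def extent_of_difference(mean_a: float, mean_b: float) -> float:
    """1 - mean_a / mean_b; positive when group b's mean is larger."""
    if mean_b == 0:
        raise ParameterError("extent undefined: reference mean is zero")
    return 1.0 - mean_a / mean_b


def compare_groups(
    m: ExpressionMatrix,
    group_a: str,
    group_b: str,
    genes: Sequence[str] = DEFAULT_MARKERS,
    combined: bool = True,
    equal_var: bool = True,
) -> list[GroupComparison]:
    """Per-gene (and optionally combined-marker) group comparison table.

    ``group_a`` is the reference group in the extent statistic (healthy in
    the healthy-vs-disease convention); expression is compared on the scale
    the matrix carries (raw by default).
    """
    if m.donor_group is None:
        raise ParameterError("matrix has no donor_group labels")
    in_a = m.donor_group == group_a
    in_b = m.donor_group == group_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ParameterError("each group needs at least 2 cells")
    targets: list[tuple[str, np.ndarray]] = [
        (g, m.gene_values(g)) for g in genes
    ]
    if combined:
        summed = m.values[:, [m.gene_index(g) for g in genes]].sum(axis=1)
        targets.append(("combined(" + "+".join(genes) + ")", summed))
    out = []
    for label, vals in targets:
        a, b = vals[in_a], vals[in_b]
        t, p = two_sample_t_test(a, b, equal_var=equal_var)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        extent = extent_of_difference(mean_a, mean_b) if mean_b != 0 else np.nan
        out.append(
            GroupComparison(
                label=label,
                mean_a=mean_a,
                mean_b=mean_b,
                t_statistic=t,
                p_value=p,
                significant=bool(p < SIGNIFICANCE_LEVEL),
                extent=float(extent),
            )
        )
    return out
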