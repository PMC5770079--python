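"""Feature (gene) selection for the cell-fate polynomial.

Two modes mirror the two ways predictor genes are chosen:

* ``correlation`` — rank all candidate genes by the absolute Spearman rank
  correlation between their expression and the death probability, and keep
  the top k.  Cross terms, when requested, pair the selected genes ranked
  by the absolute Spearman correlation between the two genes' expression.
* ``pathway`` — a fixed, knowledge-driven gene list (by default the 32
  common apoptosis-pathway genes) with cross terms given by known
  transcription-regulation pairs (e.g. TP53 regulates MDM2).

Spearman's rho is the Pearson correlation of average ranks; it captures
monotone association and is invariant under strictly increasing transforms
of either variable, which makes it robust to the skew of RPKM data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import scipy.stats

from .errors import ConfigError, ParameterError, UndefinedCorrelationError
from .io import ExpressionMatrix
from .labeling import FateLabels

#: The 32 most common apoptosis-pathway genes used in pathway mode.
APOPTOSIS_GENES: tuple[str, ...] = (
    "APAF1", "ATF4", "BAK1", "BAX", "BCL2", "BCL2L1", "BID", "CAPN1",
    "CAPN2", "CASP8", "CASP9", "CASP10", "CYCS", "DAXX", "DDIT3", "DIABLO",
    "EIF2AK3", "EIF2S1", "ERN1", "FADD", "FAS", "ITPR1", "MAP3K5", "MAPK8",
    "MAPK9", "MAPK10", "MDM2", "TNFRSF1A", "TRADD", "TRAF2", "TP53", "XIAP",
)

#: Default transcription-regulation cross-term pairs (a repository choice;
#: only TP53-MDM2 is fixed by the pathway description, the other five are
#: standard regulatory relationships among the listed genes).
DEFAULT_REGULATORY_PAIRS: tuple[tuple[str, str], ...] = (
    ("TP53", "MDM2"),
    ("TP53", "BAX"),
    ("TP53", "BCL2"),
    ("TP53", "FAS"),
    ("ATF4", "DDIT3"),
    ("DDIT3", "BCL2"),
)


@dataclass(frozen=True)
class CorrelationResult:
    """One gene's Spearman correlation with the death probability."""

    gene_id: str
    rho: float
    abs_rank: int  # 1 = strongest |rho|


@dataclass
class FeatureSet:
    """Ordered predictor genes plus optional cross-term pairs.

    Gene order encodes importance (rank 1 first); every cross-pair member
    must appear in ``genes``.
    """

    genes: list[str]
    cross_pairs: list[tuple[str, str]] = field(default_factory=list)
    mode: Literal["correlation", "pathway"] = "correlation"
    rho: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ConfigError("feature genes must be unique")
        gene_set = set(self.genes)
        for a, b in self.cross_pairs:
            if a not in gene_set or b not in gene_set:
                raise ConfigError(f"cross pair ({a}, {b}) not within feature genes")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation of two equal-length vectors.

    Average ranks are assigned to ties; a constant vector makes the rank
    standard deviation zero and the coefficient undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ParameterError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input vector")
    return float(scipy.stats.spearmanr(x, y).statistic)


def _rho_vs_vector(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|columns of values| x 1 Spearman correlations against y, vectorised.

    Constant columns get rho = 0 (no monotone association to measure);
    a constant y is an error because every gene would be undefined.
    """
    if np.ptp(y) == 0:
        raise UndefinedCorrelationError("labels are constant on this subset")
    ry = scipy.stats.rankdata(y)
    rx = scipy.stats.rankdata(values, axis=0)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, rx.T @ ry / np.where(denom > 0, denom, 1.0), 0.0)
    return rho


def correlate_genes(m: ExpressionMatrix, labels: FateLabels) -> list[CorrelationResult]:
    """Spearman correlation of every gene with p_death, with |rho| ranks."""
    rho = _rho_vs_vector(m.values, labels.p_death)
    order = np.argsort(-np.abs(rho), kind="stable")  # ties keep input gene order
    ranks = np.empty(len(rho), dtype=int)
    ranks[order] = np.arange(1, len(rho) + 1)
    return [
        CorrelationResult(g, float(r), int(k))
        for g, r, k in zip(m.gene_ids, rho, ranks)
    ]


def select_top_correlated(
    m: ExpressionMatrix, labels: FateLabels, k: int
) -> FeatureSet:
    """Top-k genes by |Spearman rho| with the death probability.

    The returned genes are in rank order (strongest first); ties in |rho|
    break by input gene order so selection is deterministic.  Marker genes
    must already be excluded by the caller.
    """
    if not 1 <= k <= m.n_genes:
        raise ParameterError(f"k={k} outside 1..{m.n_genes}")
    rho = _rho_vs_vector(m.values, labels.p_death)
    order = np.argsort(-np.abs(rho), kind="stable")[:k]
    return FeatureSet(
        genes=[m.gene_ids[i] for i in order],
        mode="correlation",
        rho={m.gene_ids[i]: float(rho[i]) for i in order},
    )


def rank_gene_pairs(
    m: ExpressionMatrix, features: FeatureSet, n_pairs: int
) -> FeatureSet:
    """Attach the top-n most inter-correlated gene pairs as cross terms.

    All unordered pairs among ``features.genes`` are ranked by the absolute
    Spearman correlation between the two genes' expression profiles; the
    strongest ``n_pairs`` become product cross terms.  Requesting more
    pairs than C(len(genes), 2) is an error (the "not applicable" cells of
    a small-gene-count grid).
    """
    genes = features.genes
    if len(genes) < 2:
        raise ParameterError("need at least 2 genes to form pairs")
    max_pairs = len(genes) * (len(genes) - 1) // 2
    if not 1 <= n_pairs <= max_pairs:
        raise ParameterError(
            f"n_pairs={n_pairs} outside 1..{max_pairs} for {len(genes)} genes"
        )
    ranks = scipy.stats.rankdata(
        m.values[:, [m.gene_index(g) for g in genes]], axis=0
    )
    corr = np.corrcoef(ranks, rowvar=False)
    scored = [
        (abs(corr[i, j]) if np.isfinite(corr[i, j]) else 0.0, i, j)
        for i, j in combinations(range(len(genes)), 2)
    ]
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))  # tie-break: gene order
    pairs = [(genes[i], genes[j]) for _, i, j in scored[:n_pairs]]
    return FeatureSet(
        genes=list(genes), cross_pairs=pairs, mode=features.mode, rho=features.rho
    )


def pathway_feature_set(
    gene_list: Sequence[str] = APOPTOSIS_GENES,
    regulatory_pairs: Sequence[tuple[str, str]] = DEFAULT_REGULATORY_PAIRS,
) -> FeatureSet:
    """Fixed pathway-mode feature set with knowledge-driven cross pairs."""
    if not gene_list:
        raise ConfigError("pathway gene list is empty")
    return FeatureSet(
        genes=list(gene_list),
        cross_pairs=[tuple(p) for p in regulatory_pairs],
        mode="pathway",
    )
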