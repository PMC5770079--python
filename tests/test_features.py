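from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polyfate as pf
from polyfate.errors import ConfigError, ParameterError, UndefinedCorrelationError

from .oracles import spearman_oracle


class TestSpearmanRho:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 2, 3, 4), (10, 20, 30, 40), 1.0),
            ((1, 2, 3, 4), (8, 6, 4, 2), -1.0),
        ],
    )
    def test_perfect_monotone(self, x, y, expected):
        assert pf.spearman_rho(x, y) == pytest.approx(expected)

    def test_tied_values_match_rank_oracle(self):
        x, y = [1, 2, 2, 4], [3, 1, 4, 5]
        assert pf.spearman_rho(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_oracle_equivalence_random_vectors_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(4, 40)
            x = rng.integers(0, 8, size=n).astype(float)  # many ties
            y = rng.integers(0, 8, size=n) + rng.random(n).round(1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert pf.spearman_rho(x, y) == pytest.approx(
                spearman_oracle(list(x), list(y)), abs=1e-12
            )

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pf.spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 20), min_size=4, max_size=25),
        st.lists(st.integers(0, 20), min_size=4, max_size=25),
    )
    def test_symmetry_and_monotone_invariance(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        rho = pf.spearman_rho(x, y)
        assert pf.spearman_rho(y, x) == pytest.approx(rho)
        # any strictly increasing transform of x leaves rho unchanged
        assert pf.spearman_rho([3 * v + 1 for v in x], y) == pytest.approx(rho)
        assert pf.spearman_rho([np.exp(v / 5) for v in x], y) == pytest.approx(rho)


def _matrix_with_labels(rng, n_cells=40, n_genes=6):
    values = rng.lognormal(size=(n_cells, n_genes))
    m = pf.ExpressionMatrix(
        values, [f"g{i}" for i in range(n_genes)], [f"c{i}" for i in range(n_cells)]
    )
    p = rng.random(n_cells)
    labels = pf.FateLabels([f"c{i}" for i in range(n_cells)], p, pf.labeling.classify(p))
    return m, labels


class TestSelectTopCorrelated:
    def test_identity_gene_ranks_first(self):
        rng = np.random.default_rng(0)
        m, labels = _matrix_with_labels(rng)
        values = np.column_stack([m.values, labels.p_death])
        m2 = pf.ExpressionMatrix(
            values, m.gene_ids + ["exact"], m.cell_ids
        )
        fs = pf.select_top_correlated(m2, labels, 3)
        assert fs.genes[0] == "exact"
        assert fs.rho["exact"] == pytest.approx(1.0)

    def test_returns_exactly_k_in_oracle_order(self):
        rng = np.random.default_rng(1)
        m, labels = _matrix_with_labels(rng, n_genes=5)
        fs = pf.select_top_correlated(m, labels, 5)
        assert len(fs.genes) == 5 and fs.mode == "correlation"
        oracle = sorted(
            m.gene_ids,
            key=lambda g: -abs(
                spearman_oracle(list(m.gene_values(g)), list(labels.p_death))
            ),
        )
        assert fs.genes == oracle

    def test_k_out_of_range(self):
        rng = np.random.default_rng(2)
        m, labels = _matrix_with_labels(rng, n_genes=4)
        with pytest.raises(ParameterError):
            pf.select_top_correlated(m, labels, 5)


class TestRankGenePairs:
    def test_exhaustive_pair_count(self):
        rng = np.random.default_rng(3)
        m, labels = _matrix_with_labels(rng, n_genes=5)
        fs = pf.select_top_correlated(m, labels, 5)
        out = pf.rank_gene_pairs(m, fs, 10)
        assert len(out.cross_pairs) == 10  # C(5,2)

    def test_too_many_pairs_rejected(self):
        rng = np.random.default_rng(4)
        m, labels = _matrix_with_labels(rng, n_genes=5)
        fs = pf.select_top_correlated(m, labels, 5)
        with pytest.raises(ParameterError):
            pf.rank_gene_pairs(m, fs, 30)

    def test_pair_order_matches_oracle(self):
        rng = np.random.default_rng(5)
        m, labels = _matrix_with_labels(rng, n_genes=4)
        fs = pf.select_top_correlated(m, labels, 4)
        out = pf.rank_gene_pairs(m, fs, 6)
        scores = {
            (a, b): abs(spearman_oracle(list(m.gene_values(a)), list(m.gene_values(b))))
            for a, b in combinations(fs.genes, 2)
        }
        oracle = sorted(scores, key=lambda p: -scores[p])
        assert sorted(map(tuple, out.cross_pairs)) == sorted(oracle)
        out_scores = [scores[tuple(p)] for p in out.cross_pairs]
        assert out_scores == sorted(out_scores, reverse=True)


class TestPathwayFeatureSet:
    def test_printed_gene_list_has_32_members(self):
        fs = pf.pathway_feature_set()
        assert len(fs.genes) == 32
        assert len(set(fs.genes)) == 32
        assert fs.mode == "pathway"

    def test_six_default_regulatory_pairs(self):
        fs = pf.pathway_feature_set()
        assert len(fs.cross_pairs) == 6
        assert ("TP53", "MDM2") in fs.cross_pairs

    def test_empty_pair_list(self):
        fs = pf.pathway_feature_set(["TP53", "MDM2"], [])
        assert fs.cross_pairs == []

    def test_pair_outside_list_rejected(self):
        with pytest.raises(ConfigError):
            pf.pathway_feature_set(["TP53"], [("TP53", "MDM2")])
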