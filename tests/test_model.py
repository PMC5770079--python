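from itertools import combinations

import numpy as np
import pytest

import polyfate as pf
from polyfate.errors import MissingGeneError, ParameterError

from .oracles import solve_normal_equations


def _matrix(values, genes):
    values = np.asarray(values, dtype=float)
    return pf.ExpressionMatrix(
        values, genes, [f"c{i}" for i in range(values.shape[0])], scale="log"
    )


class TestBuildDesignMatrix:
    @pytest.mark.parametrize(
        "degree,n_pairs,expected_cols",
        [(1, 0, 33), (2, 0, 65), (3, 0, 97), (2, 6, 71)],
    )
    def test_pathway_parameter_counts(self, degree, n_pairs, expected_cols):
        """32 pathway genes give 33/65/97 columns at degrees 1-3 and 71
        for the quadratic with six regulatory cross terms."""
        genes = pf.APOPTOSIS_GENES
        pairs = pf.DEFAULT_REGULATORY_PAIRS[:n_pairs]
        spec = pf.PolynomialSpec(degree, genes, pairs)
        rng = np.random.default_rng(0)
        m = _matrix(rng.random((5, 32)), list(genes))
        design = pf.build_design_matrix(m, spec)
        assert design.shape == (5, expected_cols)
        assert spec.n_params == expected_cols

    def test_single_gene_cubic_enumeration(self):
        m = _matrix([[2.0], [3.0]], ["g"])
        design = pf.build_design_matrix(m, pf.PolynomialSpec(3, ("g",)))
        np.testing.assert_allclose(design, [[1, 2, 4, 8], [1, 3, 9, 27]])

    def test_column_order_with_cross_term(self):
        m = _matrix([[2.0, 3.0]], ["a", "b"])
        spec = pf.PolynomialSpec(2, ("a", "b"), (("a", "b"),))
        np.testing.assert_allclose(
            pf.build_design_matrix(m, spec), [[1, 2, 3, 4, 9, 6]]
        )

    def test_missing_gene(self):
        m = _matrix([[1.0]], ["a"])
        with pytest.raises(MissingGeneError):
            pf.build_design_matrix(m, pf.PolynomialSpec(1, ("a", "zz")))

    def test_n_params_formula_exhaustive(self):
        for l in range(1, 6):
            genes = tuple(f"g{i}" for i in range(l))
            all_pairs = list(combinations(genes, 2))
            for degree in (1, 2, 3):
                for m_pairs in range(len(all_pairs) + 1):
                    spec = pf.PolynomialSpec(degree, genes, all_pairs[:m_pairs])
                    assert spec.n_params == 1 + l * degree + m_pairs


class TestFitLeastSquares:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(7)
        x = rng.random((30, 2))
        m = _matrix(x, ["x1", "x2"])
        p = 0.1 + 0.3 * x[:, 0] - 0.2 * x[:, 1]
        fitted = pf.fit_model(m, p, pf.PolynomialSpec(1, ("x1", "x2")))
        np.testing.assert_allclose(fitted.coefficients, [0.1, 0.3, -0.2], atol=1e-10)

    def test_constant_response(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng.random((20, 2)), ["x1", "x2"])
        fitted = pf.fit_model(m, np.full(20, 0.7), pf.PolynomialSpec(1, ("x1", "x2")))
        np.testing.assert_allclose(fitted.coefficients, [0.7, 0, 0], atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        design = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        fitted = pf.fit_least_squares(design, y)
        oracle = solve_normal_equations(design.tolist(), y.tolist())
        np.testing.assert_allclose(fitted.coefficients, oracle, rtol=1e-8)

    def test_rank_deficient_warns_minimum_norm(self):
        design = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with pytest.warns(UserWarning, match="rank-deficient"):
            fitted = pf.fit_least_squares(design, np.array([1.0, 2.0, 3.0]))
        assert fitted.rank == 1

    def test_under_determined_warns(self):
        with pytest.warns(UserWarning):
            pf.fit_least_squares(np.ones((2, 3)), np.ones(2))

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(10)
        design = rng.random((50, 4))
        y = rng.random(50)
        fitted = pf.fit_least_squares(design, y)
        resid = y - design @ fitted.coefficients
        assert np.abs(design.T @ resid).max() < 1e-6

    def test_adding_column_never_increases_rss(self):
        rng = np.random.default_rng(11)
        design = rng.random((40, 3))
        y = rng.random(40)
        small = pf.fit_least_squares(design, y)
        big = pf.fit_least_squares(np.column_stack([design, rng.random(40)]), y)
        assert big.residual_sumsq <= small.residual_sumsq + 1e-12


class TestPredict:
    def test_interpolates_training_data(self):
        rng = np.random.default_rng(12)
        x = rng.random((25, 3))
        m = _matrix(x, ["a", "b", "c"])
        p = 0.2 + x @ [0.5, -0.3, 0.1]
        fitted = pf.fit_model(m, p, pf.PolynomialSpec(1, ("a", "b", "c")))
        np.testing.assert_allclose(pf.predict(fitted, m), p, atol=1e-10)

    def test_all_zero_row_gives_intercept(self):
        spec = pf.PolynomialSpec(2, ("a", "b"), (("a", "b"),))
        model = pf.FittedModel(spec, np.array([0.42, 1, 2, 3, 4, 5.0]))
        m = _matrix([[0.0, 0.0]], ["a", "b"])
        assert pf.predict(model, m)[0] == pytest.approx(0.42)

    def test_hand_dot_product(self):
        spec = pf.PolynomialSpec(1, ("a", "b"))
        model = pf.FittedModel(spec, np.array([0.1, 0.3, -0.2]))
        m = _matrix([[1.0, 2.0]], ["a", "b"])
        assert pf.predict(model, m)[0] == pytest.approx(0.0)


def test_model_json_round_trip(tmp_path):
    spec = pf.PolynomialSpec(2, ("a", "b"), (("a", "b"),))
    model = pf.FittedModel(spec, np.arange(6, dtype=float), rank=6, residual_sumsq=0.5)
    path = tmp_path / "m.json"
    model.save(path)
    back = pf.FittedModel.load(path)
    assert back.spec == spec
    np.testing.assert_allclose(back.coefficients, model.coefficients)
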