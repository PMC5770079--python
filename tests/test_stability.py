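import numpy as np
import pytest
import scipy.stats

import polyfate as pf
from polyfate.errors import ParameterError


def _linear_model(coefs, genes=("a", "b")):
    spec = pf.PolynomialSpec(1, tuple(genes))
    return pf.FittedModel(spec, np.asarray(coefs, dtype=float))


class TestSampleStabilityPoints:
    def test_within_observed_ranges(self, sim_small):
        _, _, predictors = sim_small
        genes = predictors.gene_ids[:4]
        pts = pf.sample_stability_points(predictors, genes, 500, seed=1)
        cols = predictors.values[:, [predictors.gene_index(g) for g in genes]]
        assert (pts >= cols.min(axis=0)).all()
        assert (pts <= cols.max(axis=0)).all()

    def test_deterministic_given_seed(self, sim_small):
        _, _, predictors = sim_small
        genes = predictors.gene_ids[:3]
        a = pf.sample_stability_points(predictors, genes, 100, seed=9)
        b = pf.sample_stability_points(predictors, genes, 100, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_constant_gene_collapses_with_warning(self):
        m = pf.ExpressionMatrix(
            [[1.0, 2.0], [1.0, 5.0]], ["flat", "g"], ["c1", "c2"]
        )
        with pytest.warns(UserWarning, match="constant"):
            pts = pf.sample_stability_points(m, ["flat", "g"], 50, seed=0)
        assert (pts[:, 0] == 1.0).all()


class TestPointPredictionVariances:
    def test_identical_models_have_zero_variance(self):
        models = [_linear_model([0.1, 0.2, 0.3])] * 100
        pts = np.random.default_rng(0).random((20, 2))
        assert pf.point_prediction_variances(models, pts).max() == 0.0

    def test_two_models_hand_variance(self):
        """Predictions 0 and 1 at a point give sample variance 0.5."""
        m0 = _linear_model([0.0, 0.0, 0.0])
        m1 = _linear_model([1.0, 0.0, 0.0])
        var = pf.point_prediction_variances([m0, m1], np.zeros((1, 2)))
        assert var[0] == pytest.approx(0.5)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        models = [_linear_model(rng.random(3)) for _ in range(5)]
        pts = rng.random((30, 2))
        a = pf.point_prediction_variances(models, pts)
        b = pf.point_prediction_variances(models[::-1], pts)
        np.testing.assert_allclose(a, b)

    def test_fewer_than_two_models(self):
        with pytest.raises(ParameterError):
            pf.point_prediction_variances([_linear_model([1, 2, 3])], np.zeros((1, 2)))


class TestComputeMVAV:
    def test_arithmetic(self):
        assert pf.compute_mvav([0.2, 0.4]) == pytest.approx(0.3)
        assert pf.compute_mvav(np.zeros(10)) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pf.compute_mvav([0.1, -0.2])

    def test_mean_bounds(self):
        rng = np.random.default_rng(2)
        v = rng.random(100)
        assert 0 <= pf.compute_mvav(v) <= v.max()


class TestParameterRangeReport:
    def test_identical_models_zero_width(self):
        models = [_linear_model([0.1, 0.2, 0.3])] * 4
        ranges = pf.parameter_range_report(models)
        np.testing.assert_allclose(ranges[:, 2], 0.0)

    def test_hand_min_max(self):
        models = [_linear_model([0.1, 1, 1]), _linear_model([0.3, 1, 1])]
        lo, hi, width = pf.parameter_range_report(models)[0]
        assert (lo, hi, width) == pytest.approx((0.1, 0.3, 0.2))

    def test_mismatched_params_rejected(self):
        a = _linear_model([0.1, 1, 1])
        b = pf.FittedModel(pf.PolynomialSpec(1, ("a",)), np.array([0.1, 1.0]))
        with pytest.raises(ParameterError):
            pf.parameter_range_report([a, b])


class TestFitVarianceDistribution:
    def test_gamma_shape_recovery(self):
        draws = scipy.stats.gamma(2.0, scale=1.0).rvs(
            10_000, random_state=np.random.default_rng(3)
        )
        fit = pf.fit_variance_distribution(draws)
        assert 1.8 <= fit.shape <= 2.2
        assert fit.passed

    def test_exponential_special_case(self):
        draws = scipy.stats.expon.rvs(
            size=10_000, random_state=np.random.default_rng(4)
        )
        fit = pf.fit_variance_distribution(draws)
        assert 0.9 <= fit.shape <= 1.1

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            pf.fit_variance_distribution(np.array([1.0, -0.5] + [1.0] * 100))

    def test_insufficient_positive_entries(self):
        with pytest.raises(ParameterError):
            pf.fit_variance_distribution(np.concatenate([np.ones(10), np.zeros(100)]))

    def test_zeros_excluded_and_counted(self):
        draws = np.concatenate([
            scipy.stats.gamma(2.0).rvs(1000, random_state=5), np.zeros(17)
        ])
        fit = pf.fit_variance_distribution(draws)
        assert fit.n_zero == 17 and fit.n_used == 1000


class TestStabilityOrdering:
    def test_mvav_zero_for_identical_models(self):
        models = [_linear_model([0.1, 0.2, 0.3])] * 10
        pts = np.random.default_rng(6).random((100, 2))
        report = pf.stability_report(models, pts)
        assert report.mvav == 0.0
        assert report.n_models == 10

    def test_more_cells_never_less_stable(self):
        """Median MVAV across seeds does not increase with training size."""
        mvavs = {n: [] for n in (150, 600)}
        for seed in range(3):
            for n in mvavs:
                data = pf.simulate_dataset(
                    pf.SimulationConfig(n_cells=n, n_genes=30, n_informative=5,
                                        seed=seed)
                )
                labels = pf.compute_death_probability(data.matrix)
                predictors = pf.ensure_log(pf.exclude_marker_genes(data.matrix))
                fs = pf.FeatureSet(genes=list(data.informative_genes), mode="pathway")
                cv = pf.run_repeated_cv(
                    predictors, labels,
                    pf.CVConfig(degree=1, mode="pathway", pathway_features=fs,
                                n_repeats=3, seed=seed),
                )
                pts = pf.sample_stability_points(
                    predictors, fs.genes, 2000, seed=seed
                )
                mvavs[n].append(pf.stability_report(cv.models, pts).mvav)
        assert np.median(mvavs[600]) <= np.median(mvavs[150])
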