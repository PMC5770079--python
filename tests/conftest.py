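import numpy as np
import pytest

import polyfate as pf


@pytest.fixture
def toy_matrix() -> pf.ExpressionMatrix:
    """Five cells x five genes (three markers + two others), raw scale."""
    values = np.array(
        [
            [0.0, 0.0, 0.0, 5.0, 1.0],
            [1.0, 0.5, 0.5, 3.0, 2.0],
            [2.0, 1.0, 1.0, 1.0, 4.0],
            [4.0, 2.0, 2.0, 0.5, 8.0],
            [0.5, 0.25, 0.25, 2.0, 0.5],
        ]
    )
    return pf.ExpressionMatrix(
        values,
        ["CASP3", "CASP6", "CASP7", "g1", "g2"],
        [f"c{i}" for i in range(5)],
    )


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated dataset shared across read-only tests."""
    data = pf.simulate_dataset(
        pf.SimulationConfig(n_cells=300, n_genes=50, seed=3)
    )
    labels = pf.compute_death_probability(data.matrix)
    predictors = pf.ensure_log(pf.exclude_marker_genes(data.matrix))
    return data, labels, predictors
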