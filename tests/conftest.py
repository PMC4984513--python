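import numpy as np
import pytest

from occugof import CovariateSet, DetectionArray, SimConfig, simulate_dataset


@pytest.fixture
def toy_data():
    """Six units, two stations, three nights, a mix of history shapes."""
    vals = np.array(
        [
            [[1, 1, 0], [0, 0, 0]],
            [[0, 0, 0], [0, 0, 0]],
            [[1, 0, 1], [1, 1, 1]],
            [[0, 1, 1], [0, 0, 1]],
            [[0, 0, 0], [1, 0, 0]],
            [[1, 1, 1], [1, 1, 0]],
        ],
        dtype=float,
    )
    return DetectionArray(vals)


@pytest.fixture
def toy_covs(toy_data):
    return CovariateSet.intercept_only(toy_data)


@pytest.fixture
def unbalanced_data():
    """Two cohorts: four complete units, two sharing a missing night."""
    vals = np.array(
        [
            [[1, 1, 0], [0, 1, 0]],
            [[0, 0, 0], [0, 0, 0]],
            [[1, 0, 1], [1, 1, 1]],
            [[0, 1, 1], [0, 0, 1]],
            [[0, 0, np.nan], [1, 0, 0]],
            [[1, 1, np.nan], [1, 1, 0]],
        ]
    )
    return DetectionArray(vals)


@pytest.fixture
def sim_null():
    """A mid-size dataset from the no-correlation model (basic truth)."""
    return simulate_dataset(
        SimConfig(n_units=50, n_spatial=4, n_temporal=4, psi=0.8, p0=0.5, p1=0.5, seed=1),
        0,
    )


@pytest.fixture
def sim_markov():
    """A dataset with strong serial correlation (p0=0.1, p1=0.9)."""
    return simulate_dataset(
        SimConfig(n_units=50, n_spatial=4, n_temporal=4, psi=0.8, p0=0.1, p1=0.9, seed=2),
        0,
    )
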