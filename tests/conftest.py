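import numpy as np
import pytest

from tsee import TimeSeriesDataset


def make_dataset(n_cells=12, n_features=3, n_stages=3, seed=0):
    """Small random dataset with equal-width stage bins; values in [0, 1]."""
    rng = np.random.default_rng(seed)
    expression = rng.uniform(0.0, 1.0, size=(n_cells, n_features))
    stage_index = 1 + (np.arange(n_cells) * n_stages) // n_cells
    if n_stages > 1:
        stage_time = (stage_index - 1) / (n_stages - 1)
    else:
        stage_time = np.zeros(n_cells)
    return TimeSeriesDataset(
        expression=expression,
        stage_index=stage_index,
        stage_time=stage_time,
    )


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
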