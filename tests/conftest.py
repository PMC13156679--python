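import numpy as np
import pytest

from scmsi import (
    SimConfig,
    simulate_experiment,
    spatial_kmeans,
    tic_normalize,
)
from scmsi.preprocess import peak_table_from_dataset


@pytest.fixture(scope="session")
def slide_config():
    """A small synthetic slide with colonies and singletons."""
    return SimConfig(grid_shape=(80, 80), n_colonies=5, n_singletons=15, seed=3)


@pytest.fixture(scope="session")
def slide(slide_config):
    """(dataset, brightfield, truth) for the shared slide."""
    return simulate_experiment(slide_config)


@pytest.fixture(scope="session")
def slide_peak_table(slide):
    ds, _, _ = slide
    return peak_table_from_dataset(tic_normalize(ds))


@pytest.fixture(scope="session")
def slide_partition(slide_peak_table):
    return spatial_kmeans(slide_peak_table, seed=0)


def truth_feature_map(pt, truth):
    """Map each aligned feature column to the nearest planted feature index."""
    return np.array([int(np.argmin(np.abs(truth.feature_mz - m))) for m in pt.features])
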