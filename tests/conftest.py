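import numpy as np
import pytest

from tissue import (
    PredictionMatrix,
    SpatialDataset,
    SimConfig,
    simulate_counts,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim():
    """Small two-group ZINB simulation for fast pipeline tests."""
    return simulate_counts(
        SimConfig(n_cells=120, n_genes=40, n_group_a=60, seed=7)
    )


@pytest.fixture
def grid_dataset(rng):
    """60 cells on a grid with mildly structured expression."""
    xs, ys = np.meshgrid(np.arange(6), np.arange(10))
    coords = np.c_[xs.ravel(), ys.ravel()].astype(float)
    values = rng.poisson(3.0, size=(60, 12)).astype(float)
    return SpatialDataset(
        values,
        coords,
        [f"c{i}" for i in range(60)],
        [f"g{j}" for j in range(12)],
    )


def make_pred(values, gene_ids=None, cell_ids=None):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(values.shape[1])]
    return PredictionMatrix(values, gene_ids, cell_ids=cell_ids)
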