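import numpy as np
import pytest

import fatescape as fs


@pytest.fixture(scope="session")
def true_params() -> fs.ModelParameters:
    return fs.ModelParameters()


@pytest.fixture(scope="session")
def reference300(true_params) -> fs.SnapshotDataset:
    """Full-scale reference dataset: 300 cells, 10 time points, LIF = 50."""
    return fs.generate_reference(true_params, n_cells=300, T=10, seed=12345)


@pytest.fixture(scope="session")
def reference100(true_params) -> fs.SnapshotDataset:
    """Reduced reference for inference tests: 100 cells, 10 time points."""
    return fs.generate_reference(true_params, n_cells=100, T=10, seed=12345)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
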