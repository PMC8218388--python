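import numpy as np
import pytest
import scipy.sparse as sp

from sparkx import CountMatrix, Coordinates, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def moderate_null_dataset():
    """Small moderate-sparsity null dataset shared by read-only tests."""
    cfg = SimulationConfig(
        n_locations=600,
        n_genes=200,
        pattern="null",
        mean=0.5,
        dispersion=0.2,
        seed=1234,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def tiny_counts():
    """4 genes x 5 locations with hand-set entries (one all-zero gene)."""
    mat = np.array(
        [
            [2, 0, 1, 0, 0],
            [0, 0, 0, 0, 0],
            [1, 1, 1, 1, 1],
            [0, 3, 0, 0, 4],
        ]
    )
    return CountMatrix(
        sp.csr_matrix(mat),
        ["Actb", "mt-Co1", "Gapdh", "Cbln1"],
        [f"loc_{i}" for i in range(5)],
    )


@pytest.fixture()
def tiny_coords():
    rng = np.random.default_rng(7)
    return Coordinates(rng.uniform(size=(5, 2)), [f"loc_{i}" for i in range(5)])
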