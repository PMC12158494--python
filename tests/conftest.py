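import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import sparse

from quiestem.bulk import BulkPair
from quiestem.simulate import SimulationConfig, simulate_bulk_pair, simulate_cells


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """Down-scaled study conditions for fast unit tests (same effect sizes)."""
    return SimulationConfig(
        n_genes=400,
        n_cells_per_study=800,
        n_dormancy_genes=20,
        n_monotone_decreasing_genes=12,
        n_peak_genes=8,
        n_late_genes=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_sim_config):
    adata, truth = simulate_cells(small_sim_config)
    return adata, truth


@pytest.fixture(scope="session")
def small_bulk_pair(small_sim_config, small_study) -> BulkPair:
    adata, truth = small_study
    return BulkPair(simulate_bulk_pair(small_sim_config, adata, truth))


@pytest.fixture()
def tiny_adata() -> AnnData:
    """4 cells x 5 genes with hand-checkable counts and two donors."""
    counts = np.array(
        [
            [10, 0, 3, 1, 0],
            [40, 0, 12, 4, 0],
            [5, 2, 0, 0, 1],
            [8, 1, 1, 2, 0],
        ]
    )
    return AnnData(
        X=sparse.csr_matrix(counts),
        obs=pd.DataFrame(
            {"donor": ["d1", "d1", "d2", "d2"]},
            index=[f"c{i}" for i in range(4)],
        ),
        var=pd.DataFrame(index=[f"g{i}" for i in range(5)]),
    )
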