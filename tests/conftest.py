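import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from axci.dataset import LAYER_NAMES, AllelicCountSet
from axci.simulate import SimulationParams, simulate_timecourse


def make_dataset(layers: dict, chromosomes=None, names=None, days=None,
                 extra_cell_cols=None) -> AllelicCountSet:
    """Small hand-built AllelicCountSet for arithmetic tests.

    ``layers`` maps layer names to dense arrays (missing layers are zero).
    """
    shape = next(iter(layers.values())).shape
    n_genes, n_cells = shape
    full = {name: sp.csr_matrix(np.asarray(layers.get(name, np.zeros(shape)), dtype=np.int64))
            for name in LAYER_NAMES}
    chromosomes = chromosomes or ["chr1"] * n_genes
    names = names or [f"g{i}" for i in range(n_genes)]
    genes = pd.DataFrame({
        "gene_id": [f"g{i:03d}" for i in range(n_genes)],
        "name": names,
        "chromosome": chromosomes,
        "start": np.arange(n_genes) * 1000 + 1,
        "end": np.arange(n_genes) * 1000 + 500,
        "is_pseudogene": False,
    })
    cells = pd.DataFrame({
        "cell_id": [f"c{i:03d}" for i in range(n_cells)],
        "time_point_days": days if days is not None else [0] * n_cells,
    })
    for col, vals in (extra_cell_cols or {}).items():
        cells[col] = vals
    return AllelicCountSet(genes, cells, full)


SMALL_PARAMS = dict(n_cells_per_day=60, n_genes_autosomal=150, n_genes_x=40,
                    mrna_target=60_000)


@pytest.fixture(scope="session")
def small_sim():
    """Fast reduced-scale simulation shared across tests."""
    return simulate_timecourse(SimulationParams(seed=11, **SMALL_PARAMS))


@pytest.fixture(scope="session")
def default_sim():
    """One study-condition-scale simulation (1500 cells, 100 X genes)."""
    return simulate_timecourse(SimulationParams(seed=5))
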