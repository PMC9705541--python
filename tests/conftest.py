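import logging

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from il2tome.config import PipelineConfig, SimulationConfig
from il2tome.datamodel_io import MultiomicsDataset
from il2tome import synthetic_data as syn

logging.getLogger("il2tome").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sim_small() -> SimulationConfig:
    """Reduced-scale cohort: full design (13 participants x 3 visits, five
    gates) with a slimmer panel for fast unit tests."""
    return SimulationConfig(cells_per_visit=1300, n_genes=120, n_proteins=30)


@pytest.fixture(scope="session")
def truth_small(sim_small):
    return syn.build_truth(sim_small)


@pytest.fixture(scope="session")
def dataset_small(truth_small, sim_small):
    dataset, _ = syn.generate_dataset(truth_small, sim_small, seed=0)
    return dataset


@pytest.fixture(scope="session")
def stim_dataset_small(truth_small, sim_small):
    dataset, _ = syn.generate_dataset(truth_small, sim_small, seed=1, stimulated=True)
    return dataset


def make_toy_dataset(n_cells=6, n_genes=4, n_proteins=3, n_tags=2, seed=0,
                     gates=None):
    """Hand-sized dataset for I/O and contract tests."""
    rng = np.random.default_rng(seed)
    gates = gates if gates is not None else ["Treg"] * n_cells
    meta = pd.DataFrame(
        {
            "participant": ["P01"] * n_cells,
            "dose": [0.32] * n_cells,
            "visit": [0] * n_cells,
            "stimulation": ["unstim"] * n_cells,
            "gate": gates,
        }
    )
    return MultiomicsDataset(
        rna_counts=sp.csr_matrix(rng.integers(0, 6, size=(n_cells, n_genes))),
        protein_counts=sp.csr_matrix(rng.integers(0, 20, size=(n_cells, n_proteins))),
        tag_counts=rng.integers(0, 3, size=(n_cells, n_tags)),
        cell_meta=meta,
        rna_features=pd.DataFrame({"name": [f"G{i}" for i in range(n_genes)]}),
        protein_features=pd.DataFrame({"name": [f"P{i}" for i in range(n_proteins)]}),
        tag_names=[f"tag{i}" for i in range(n_tags)],
    )


@pytest.fixture
def toy_dataset():
    return make_toy_dataset()
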