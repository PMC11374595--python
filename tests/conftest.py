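import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mirsource import sc_core
from mirsource.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def sim(config):
    """One full synthetic study shared across read-only tests."""
    return simulate_all(config)


@pytest.fixture(scope="session")
def norm_dataset(sim):
    """QC'd and normalized copy of the simulated expression dataset."""
    adata = sim.dataset.copy()
    sc_core.annotate_cells(adata)
    filtered, _ = sc_core.qc_filter(adata, min_genes=10, min_counts=10, max_mito=1.0)
    return sc_core.normalize(filtered)


def make_adata(counts, cell_types=None, subtypes=None, states=None, genes=None):
    """Small dense-count AnnData builder for toy tests."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = list(genes) if genes is not None else [f"G{j}" for j in range(n_genes)]
    obs = pd.DataFrame(
        {
            "cell_type": cell_types if cell_types is not None else ["t"] * n_cells,
            "cell_subtype": subtypes if subtypes is not None else ["t.1"] * n_cells,
            "disease_state": states if states is not None else ["Heal"] * n_cells,
        },
        index=[f"C{i}" for i in range(n_cells)],
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(counts), obs=obs, var=pd.DataFrame(index=pd.Index(genes))
    )
    return sc_core.annotate_cells(adata)
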