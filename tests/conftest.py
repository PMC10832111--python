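import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import tmekit as tk


def build_adata(lognorm, clusters, genes=None, majors=None, patients=None):
    """Construct a minimal cell table with a given log-normalized layer."""
    lognorm = np.asarray(lognorm, float)
    n, g = lognorm.shape
    genes = genes or [f"g{j}" for j in range(g)]
    obs = pd.DataFrame(
        {
            "cluster_label": list(clusters),
            "major_type": list(majors) if majors is not None else ["m0"] * n,
            "patient_id": list(patients) if patients is not None else ["p0"] * n,
        },
        index=[f"c{i}" for i in range(n)],
    )
    adata = ad.AnnData(
        X=sparse.csr_matrix(lognorm), obs=obs, var=pd.DataFrame(index=pd.Index(genes))
    )
    adata.layers["lognorm"] = sparse.csr_matrix(lognorm)
    return adata


@pytest.fixture(scope="session")
def fold8():
    """Four planted clusters, eight-fold markers, normalized; shared read-only."""
    cfg = tk.SimConfig(
        n_clusters=4, n_cells_per_cluster=100, n_genes=300, marker_fold_change=8.0, seed=1
    )
    cells, gt = tk.simulate_cells(cfg)
    return tk.normalize_log(cells), gt, cfg


@pytest.fixture(scope="session")
def cycling_sim():
    """Fold-8 clusters with a 10% cycling population, normalized."""
    cfg = tk.SimConfig(
        n_clusters=4,
        n_cells_per_cluster=250,
        n_genes=1000,
        marker_fold_change=8.0,
        cycling_fraction=0.1,
        seed=3,
    )
    cells, gt = tk.simulate_cells(cfg)
    return tk.normalize_log(cells), gt, cfg
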