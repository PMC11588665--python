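import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from skintx.simulate import CohortConfig, GradientSpec, SpotGridConfig, simulate_cohort, simulate_spots


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort reused by read-only tests (3 donors, 150 cells each)."""
    cfg = CohortConfig(n_donors=3, n_cells_per_donor=150, n_genes=1150, seed=0)
    return cfg, *simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the package's default study conditions."""
    cfg = CohortConfig(seed=0)
    return cfg, *simulate_cohort(cfg)


@pytest.fixture(scope="session")
def gradient_grid():
    """Noise-light grid with a planted linear tumor-abundance decay and debris."""
    cfg = SpotGridConfig(
        rows=18,
        cols=12,
        epidermis_depth=1,
        debris_size=5,
        noise_sd=0.01,
        gradients={
            "Tumor": GradientSpec("linear", base=1.0, slope=0.05),
            "Keratinocyte": GradientSpec("linear", base=2.0, slope=0.1),
        },
        seed=0,
    )
    return cfg, *simulate_spots(cfg)


def make_adata(counts, obs=None, symbols=None):
    """Small AnnData helper for hand-crafted matrices."""
    counts = np.asarray(counts)
    n, g = counts.shape
    var = pd.DataFrame(index=pd.Index([f"g{j}" for j in range(g)], name="gene_id"))
    var["symbol"] = symbols if symbols is not None else list(var.index)
    obs = obs if obs is not None else pd.DataFrame(
        index=pd.Index([f"c{i}" for i in range(n)], name="barcode")
    )
    return AnnData(X=sp.csr_matrix(counts.astype(np.int32)), obs=obs, var=var)
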