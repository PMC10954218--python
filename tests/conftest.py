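import numpy as np
import pytest

from gastrufate import qc as qcm
from gastrufate.simdata import SimConfig, simulate_branching_lineage


@pytest.fixture(scope="session")
def small_sim():
    """Small two-genotype cohort shared by read-only tests."""
    cfg = SimConfig(n_samples_per_genotype=2, n_cells_per_sample=300, seed=42)
    return simulate_branching_lineage(cfg)


@pytest.fixture(scope="session")
def small_sim_norm(small_sim):
    """Same cohort with lognorm and Pearson layers attached."""
    adata = qcm.log_normalize(small_sim.adata)
    adata = qcm.normalize(adata)
    return adata


@pytest.fixture(scope="session")
def wt_sim():
    """Single genotype, 7 balanced well-separated populations (clustering)."""
    from gastrufate.simdata import well_separated_config

    out = simulate_branching_lineage(well_separated_config(seed=7))
    adata = out.adata[(out.adata.obs["genotype"] == "wt").to_numpy()].copy()
    return qcm.normalize(qcm.log_normalize(adata))


def rng(seed=0):
    return np.random.default_rng(seed)
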