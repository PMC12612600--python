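import numpy as np
import pandas as pd
import pytest

from orchardqg.genomics import GrMatrix, grm_yang, stabilize_psd
from orchardqg.synthetic import (
    OrchardDesign,
    SimulationConfig,
    simulate_genotypes,
    simulate_orchard_design,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_study():
    """A small single-site study: 12 clones, 60 ramets, 800 SNPs."""
    cfg = SimulationConfig(
        n_clones=12, ramets_per_site=60, n_sites=1, grid_rows=8, grid_cols=8,
        n_snps=800, true_genetic_variance=0.3, true_spatial_variance=0.15,
        spatial_rho_col=0.4, spatial_rho_row=0.4, true_nugget=0.55, seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def two_site_study():
    cfg = SimulationConfig(
        n_clones=14, site_clone_counts=(12, 10), n_shared_clones=8,
        ramets_per_site=(60, 48), n_sites=2, grid_rows=8, grid_cols=8,
        n_snps=800, true_genetic_variance=0.3,
        cross_site_genetic_correlation=0.8,
        true_spatial_variance=0.15, spatial_rho_col=0.4, spatial_rho_row=0.4,
        true_nugget=0.55, seed=7,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def tiny_grm():
    """GRM over 5 clones from 400 simulated SNPs, PSD-stabilized."""
    geno = simulate_genotypes(5, 400, seed=11)
    return stabilize_psd(grm_yang(geno), jitter=1e-4)


@pytest.fixture()
def identity_grm():
    def make(n):
        return GrMatrix(
            clone_ids=np.array([f"C{i + 1:03d}" for i in range(n)], dtype=object),
            values=np.eye(n),
            n_snps_used=0,
        )

    return make


@pytest.fixture()
def toy_design():
    """A hand-written 12-ramet, 4-clone, one-site design on a 4x3 grid."""
    rows = []
    k = 0
    for r in range(1, 5):
        for c in range(1, 4):
            k += 1
            rows.append(
                {
                    "ramet_id": f"R{k:05d}", "site": "S1", "row": r, "col": c,
                    "clone": f"C{(k - 1) % 4 + 1:03d}", "population": "P1",
                }
            )
    return OrchardDesign(table=pd.DataFrame(rows))
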