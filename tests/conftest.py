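import numpy as np
import pandas as pd
import pytest

from cardiofusion import sim as simmod
from cardiofusion import SimConfig


@pytest.fixture(scope="session")
def clean_bundle():
    """Zero-dropout, near-zero-error 4-clade cohort with fused cells."""
    cfg = SimConfig(
        n_clades=4,
        ssnvs_per_branch=2,
        panel_size=30,
        n_cells_by_ploidy={"diploid": 30, "tetraploid": 30, "higher": 20},
        allelic_dropout=0.0,
        locus_dropout=0.0,
        base_error=1e-9,
        seed=1,
    )
    return simmod.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def dropout_bundle():
    """Default study-condition cohort (9 clades, dropout, fusion, doublets)."""
    return simmod.simulate_dataset(SimConfig(seed=7))


def make_genotype_frame(n_het: int, n_althom: int, n_refhom: int = 0) -> pd.DataFrame:
    """Genotyped CALLED records with prescribed max-posterior classes."""
    rows = []
    for i in range(n_het):
        rows.append(("c%d" % i, "s0", 100, 50, 0.003, 0.0, 0.99, 0.01, "CALLED"))
    for i in range(n_althom):
        rows.append(("h%d" % i, "s0", 100, 99, 0.003, 0.0, 0.01, 0.99, "CALLED"))
    for i in range(n_refhom):
        rows.append(("r%d" % i, "s0", 100, 0, 0.003, 0.99, 0.01, 0.0, "ABSENT"))
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "site_id", "depth", "alt_count", "mean_base_error",
            "p_refhom", "p_het", "p_althom", "call",
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
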