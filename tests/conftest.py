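import numpy as np
import pandas as pd
import pytest

from mirwin import PanelSpec, gen_reference_panel


@pytest.fixture(scope="session")
def small_panel():
    """3-block diploid panel, 200 subjects, moderate LD."""
    spec = PanelSpec(n_haplotypes=400, n_snps_per_block=10, n_blocks=3,
                     block_rho=0.5, seed=11)
    return gen_reference_panel(spec)


@pytest.fixture(scope="session")
def big_panel():
    """1,000-subject panel used for LD-recovery checks."""
    spec = PanelSpec(n_haplotypes=2_000, n_snps_per_block=20, n_blocks=4,
                     block_rho=0.5, seed=7)
    return gen_reference_panel(spec)


@pytest.fixture()
def sumstats_frame():
    """Tiny hand-built summary-statistic table on two chromosomes."""
    return pd.DataFrame({
        "SNP": ["rs1", "rs2", "rs3", "rs4", "rs5"],
        "CHR": ["1", "1", "1", "2", "2"],
        "BP": [80_000, 120_000, 120_001, 50_000, 60_000],
        "P": [0.01, 0.2, 0.5, 0.04, 0.9],
    })


def ar1_matrix(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])
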