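import numpy as np
import pandas as pd
import pytest

from cnvsleep import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully-featured synthetic cohort shared across tests."""
    cfg = SimConfig(
        n_individuals=800,
        n_genes=400,
        genome_length=40_000_000,
        recurrent_carrier_freq=0.03,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_genes():
    """Three genes on chromosome 1; g3 has no LOEUF annotation."""
    return pd.DataFrame(
        {
            "chrom": ["1", "1", "1"],
            "start": [100, 500, 1000],
            "end": [200, 800, 1500],
            "gene_id": ["g1", "g2", "g3"],
            "loeuf": [0.1, 0.5, np.nan],
        }
    )


def make_calls(rows):
    return pd.DataFrame(
        rows, columns=["individual_id", "chrom", "start", "end", "cnv_type"]
    )
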