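import numpy as np
import pandas as pd
import pytest

from signature_ifs.synthetic_data import SimulationConfig, simulate

#: the three-level category codes produced by values +/-10 around 0 at t=1
TEN = 10.0


@pytest.fixture(scope="session")
def small_dataset():
    """A small but informative four-group cohort shared across tests."""
    config = SimulationConfig(
        n_genes=60, group_sizes=(8, 8, 8, 8),
        n_subtype_genes=4, n_survival_genes=4, n_shared_genes=0,
        effect_size=3.0, hazard_ratio=4.0, seed=11)
    return simulate(config)


def random_categories(rng, n, k=3):
    """Random category vector over k symbols as plain ints."""
    return rng.integers(-1, -1 + k, size=n)


def make_expression(values, gene_ids=None, sample_ids=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=samples)
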