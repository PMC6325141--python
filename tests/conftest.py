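import numpy as np
import pandas as pd
import pytest

import crickspace as cs


@pytest.fixture(scope="session")
def yeast():
    return cs.load_constants("s_cerevisiae")


@pytest.fixture(scope="session")
def ecoli():
    return cs.load_constants("e_coli")


@pytest.fixture(scope="session")
def all_presets():
    return [cs.load_constants(name) for name in cs.preset_names()]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_gene_table(yeast):
    """A 400-gene synthetic table with no planted boundary."""
    spec = cs.GeneTableSpec(n_genes=400, seed=77)
    return cs.generate_gene_table(spec, yeast)


@pytest.fixture(scope="session")
def rates_frame():
    """A tiny hand-specified rates table for geometric operations."""
    beta_m = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 1.0, 3.0, 8.0, 30.0])
    beta_p = np.array([100.0, 30.0, 250.0, 40.0, 800.0, 500.0, 7.0, 90.0, 640.0, 3000.0])
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(10)],
            "beta_m": beta_m,
            "beta_p": beta_p,
            "m": beta_m / 5.1,
            "p": beta_m * beta_p / (5.1 * 1.34),
        }
    )
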