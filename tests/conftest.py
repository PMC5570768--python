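import numpy as np
import pandas as pd
import pytest

from metabatch import SimulationConfig, load_sle_pcorr

BATCH_COLS = ["pcorr_batch1", "pcorr_batch2", "pcorr_batch3"]


@pytest.fixture(scope="session")
def sle_table() -> pd.DataFrame:
    """Bundled three-batch p(corr) reference profile (73 metabolites)."""
    return load_sle_pcorr()


@pytest.fixture(scope="session")
def sle_pcorr(sle_table) -> pd.DataFrame:
    """K x 3 per-batch p(corr) matrix from the bundled table."""
    return sle_table[BATCH_COLS]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture()
def two_class_data(rng):
    """40 samples x 15 metabolites with a strong effect on the first column."""
    y = np.array(["control"] * 20 + ["case"] * 20)
    X = rng.standard_normal((40, 15))
    X[:, 0] += (y == "case") * 2.0
    X[:, 1] -= (y == "case") * 1.5
    ids = [f"s{i:02d}" for i in range(40)]
    return pd.DataFrame(X, index=ids, columns=[f"m{k:02d}" for k in range(15)]), \
        pd.Series(y, index=ids)


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic study shared across tests (cheap to generate)."""
    return SimulationConfig(seed=7, n_per_group=8, n_descriptors=40,
                            k_metabolites=24, n_is=5, n_batches=3)
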