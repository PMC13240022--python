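import numpy as np
import pandas as pd
import pytest

from regfate import SyntheticDesign, generate_single_cell_dataset


@pytest.fixture(scope="session")
def small_design():
    return SyntheticDesign(n_cells=600, n_genes=500, n_regulons=24,
                           n_state_specific_per_state=4,
                           regulon_size_range=(8, 15),
                           activity_noise_sd=0.0, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """Noise-free planted dataset shared across tests (read-only)."""
    return generate_single_cell_dataset(small_design)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_activity(rng):
    """A 40-cell × 8-regulon positive activity matrix."""
    values = rng.uniform(0.01, 1.0, size=(40, 8))
    return pd.DataFrame(values, columns=[f"R{j}" for j in range(8)])
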