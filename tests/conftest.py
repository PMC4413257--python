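import numpy as np
import pandas as pd
import pytest

from subtypenet._utils import BASAL, LUMINAL
from subtypenet.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """Small cohort: fast but still exercises every pipeline stage."""
    return SimulationConfig(
        n_luminal=14, n_basal=12, n_chroms=4, n_probes_per_chrom=200,
        n_true_pairs=16, n_decoy_pairs=16, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The study-shaped default cohort (52 luminal-A + 40 basal-like)."""
    return simulate_dataset(SimulationConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def two_group_labels(n_l: int, n_b: int) -> pd.Series:
    names = [f"L{i}" for i in range(n_l)] + [f"B{i}" for i in range(n_b)]
    return pd.Series([LUMINAL] * n_l + [BASAL] * n_b, index=names,
                     name="subtype")
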