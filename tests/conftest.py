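import numpy as np
import pandas as pd
import pytest

from panenrich.ingest import DEFAULT_H3_SCHEME, FrameworkScheme
from panenrich.panning_sim import PanningSimConfig, simulate_panning


@pytest.fixture(scope="session")
def h3_scheme() -> FrameworkScheme:
    return DEFAULT_H3_SCHEME


@pytest.fixture(scope="session")
def small_panning():
    """A small planted panning experiment shared across tests."""
    return simulate_panning(
        PanningSimConfig(n_clones=200, reads_per_repertoire=20_000, seed=3)
    )


@pytest.fixture(scope="session")
def reference_panning():
    """The reference study condition: 5,000 length-9 clones, 1e6 reads/rep."""
    return simulate_panning(PanningSimConfig(seed=123))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
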