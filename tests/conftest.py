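import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from disparitree.io_formats import read_dated_tree
from disparitree.synthetic import SimConfig, simulate_dataset


@pytest.fixture
def three_taxon_tree():
    """((A,B),C) with the inner split at 1 Ma and root at 2 Ma, all tips extant."""
    return read_dated_tree(data="((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated dataset shared by read-only tests."""
    cfg = SimConfig(
        seed=11,
        min_tips=25,
        max_tips=40,
        n_characters=60,
        missing_fraction=0.3,
        clock_sd=0.0,
        clock_mean=0.02,
    )
    tree, records, matrix, truth = simulate_dataset(cfg)
    return cfg, tree, records, matrix, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
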