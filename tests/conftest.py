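import numpy as np
import pytest

from envshift import Arena, truncate_triplet
from envshift.synthetic_data import SimConfig, generate_triplet


@pytest.fixture(scope="session")
def square_arena():
    return Arena(shape="square", extent=125.0)


@pytest.fixture(scope="session")
def default_triplet():
    """A 200-cell object triplet at the study defaults, truncated to 765 s,
    with its ground truth.  Shared (read-only) across the suite."""
    triplet, truth = generate_triplet(SimConfig(seed=1))
    return truncate_triplet(triplet), truth


@pytest.fixture(scope="session")
def small_triplet():
    """A cheap 12-cell triplet for pipeline/IO tests."""
    cfg = SimConfig(n_cells=12, fraction_increase=0.25, fraction_decrease=0.25, seed=4)
    triplet, truth = generate_triplet(cfg)
    return triplet, truth


@pytest.fixture(scope="session")
def trajectory(square_arena):
    from envshift import simulate_trajectory

    return simulate_trajectory(square_arena, 765.0, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
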