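import numpy as np
import pytest

from linkrisk.network_io import WeightedBipartiteNetwork, assemble_link_table


@pytest.fixture
def two_by_two() -> WeightedBipartiteNetwork:
    """Fully connected 2x2 network with unit weights."""
    return WeightedBipartiteNetwork(
        "tiny", "pollination", ["p0", "p1"], ["a0", "a1"], np.ones((2, 2))
    )


@pytest.fixture
def double_star() -> WeightedBipartiteNetwork:
    """Two disjoint stars: every animal is a specialist of one of two plants."""
    w = np.zeros((2, 8))
    w[0, :4] = 1.0
    w[1, 4:] = 1.0
    return WeightedBipartiteNetwork(
        "stars", "pollination", ["p0", "p1"], [f"a{i}" for i in range(8)], w
    )


@pytest.fixture
def random_10x15() -> WeightedBipartiteNetwork:
    """10 plants x 15 animals random weighted network, no isolated species."""
    rng = np.random.default_rng(2024)
    while True:
        w = (rng.random((10, 15)) < 0.25) * rng.integers(1, 200, (10, 15))
        if w.sum(axis=1).min() > 0 and w.sum(axis=0).min() > 0:
            break
    return WeightedBipartiteNetwork(
        "r10x15", "seed_dispersal",
        [f"p{i}" for i in range(10)], [f"a{j}" for j in range(15)], w.astype(float),
    )


@pytest.fixture
def linked_table(random_10x15):
    return assemble_link_table([random_10x15])
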