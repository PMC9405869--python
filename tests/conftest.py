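import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from funconn.connectivity import WeightedNetwork
from funconn.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_925)


@pytest.fixture
def unit_path3():
    """Three nodes in a line, unit weights."""
    w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return WeightedNetwork(w)


@pytest.fixture
def k4():
    """Complete unit-weight graph on 4 nodes."""
    return WeightedNetwork(np.ones((4, 4)) - np.eye(4))


@pytest.fixture
def two_cliques():
    """Two disconnected unit-weight triangles (component partition has Q = 0.5)."""
    w = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for a in block:
            for b in block:
                if a != b:
                    w[a, b] = 1.0
    return WeightedNetwork(w)


@pytest.fixture
def tiny_cohort_config():
    """Small, fast synthetic cohort for end-to-end tests."""
    return SyntheticConfig(
        n_subjects=6,
        n_nodes=20,
        n_timepoints=80,
        n_communities=2,
        neighbourhood_size=4,
        effect_delta=0.0,
        seed=11,
    )
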