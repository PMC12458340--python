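import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from strainbiogeo import DistanceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_distance_matrix(rng, n, labels=None, scale=1.0):
    """Random symmetric hollow matrix with iid uniform off-diagonals."""
    vals = rng.uniform(0.05, scale, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    if labels is None:
        labels = [f"s{i}" for i in range(n)]
    return DistanceMatrix(vals, labels)


@pytest.fixture
def dm_factory(rng):
    def make(n, labels=None, scale=1.0):
        return random_distance_matrix(rng, n, labels, scale)

    return make
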