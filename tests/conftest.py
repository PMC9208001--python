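import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from hierconn.netbuild import ConnectivityMatrix, ThresholdedNetwork, threshold_proportional


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(n: int, rng: np.random.Generator) -> np.ndarray:
    w = rng.random((n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


def as_network(weights: np.ndarray, sparsity: float | None = None) -> ThresholdedNetwork:
    """Wrap a symmetric weight matrix; optionally threshold to a density."""
    labels = [f"n{i:02d}" for i in range(weights.shape[0])]
    cm = ConnectivityMatrix(weights, labels)
    if sparsity is not None:
        return threshold_proportional(cm, sparsity)
    n_edges = int(np.count_nonzero(np.triu(weights, 1)))
    return ThresholdedNetwork(weights, labels, sparsity=1.0, n_edges=n_edges)


@pytest.fixture
def small_cohort():
    """A small planted-effect cohort shared by slower tests."""
    from hierconn.simcohort import SimConfig, simulate_cohort

    cfg = SimConfig(n_controls=12, n_patients=10, n_timepoints=150, seed=99)
    return cfg, simulate_cohort(cfg)
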