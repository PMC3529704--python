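import numpy as np
import pytest

from ccit.core import (
    DelayAnnotatedNetwork,
    GeneTable,
    LaggedArc,
    TimeSeriesDataset,
)


@pytest.fixture
def worked_example_network():
    """Four-gene network with two instantaneous and two first-order arcs:
    A->B (lag 0), D->B (lag 0), C->B (lag 1), D->A (lag 1); all genes
    3-level."""
    table = GeneTable.uniform(["A", "B", "C", "D"], 3)
    arcs = {
        LaggedArc(0, 1, 0),
        LaggedArc(3, 1, 0),
        LaggedArc(2, 1, 1),
        LaggedArc(3, 0, 1),
    }
    return DelayAnnotatedNetwork(table, arcs, d_max=1)


@pytest.fixture
def worked_example_dataset(worked_example_network):
    """Periodic 3-level data where B really depends on A, D and lagged C."""
    rng = np.random.default_rng(42)
    n, N = 4, 60
    arr = np.zeros((n, N), dtype=np.int64)
    arr[2] = rng.integers(0, 3, N)  # C: root
    arr[3] = rng.integers(0, 3, N)  # D: root
    for t in range(N):
        # A depends on D one step back (wrap: data treated as periodic)
        a_src = arr[3, (t - 1) % N]
        arr[0, t] = (a_src + rng.integers(0, 2)) % 3
        b_src = (arr[0, t] + arr[3, t] + arr[2, (t - 1) % N]) % 3
        arr[1, t] = b_src if rng.random() < 0.8 else rng.integers(0, 3)
    return TimeSeriesDataset([arr], worked_example_network.gene_table, periodic=True)


@pytest.fixture
def binary_table():
    return GeneTable.uniform(["A", "B", "C"], 2)
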