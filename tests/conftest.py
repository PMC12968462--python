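import numpy as np
import pytest

from netreconf.communities import AssignmentMatrix
from netreconf.io import NETWORKS, AtlasLabels, ParcellatedSeries


@pytest.fixture
def fig_worked_example():
    """Seven regions, four windows, four networks: the canonical worked
    example of the four reconfiguration measures.

    Region 1 visits 3 of 4 networks (two lone switches); region 2 switches
    at every transition, twice jointly with region 4; region 3 switches
    once; regions 5 and 7 move together at all three transitions; region 6
    never moves.
    """
    labels = np.array([
        [1, 1, 2, 3],   # region 1
        [1, 2, 3, 4],   # region 2
        [2, 2, 2, 4],   # region 3
        [1, 2, 3, 1],   # region 4
        [3, 4, 1, 2],   # region 5
        [4, 4, 4, 4],   # region 6
        [3, 4, 1, 2],   # region 7
    ])
    return AssignmentMatrix(labels, 4, [f"r{i}" for i in range(1, 8)])


@pytest.fixture
def small_atlas():
    """16 regions over 4 networks, 4 regions each."""
    mapping = {f"R{i:02d}": NETWORKS[i // 4] for i in range(16)}
    return AtlasLabels(mapping)


@pytest.fixture
def small_series(small_atlas):
    """16-region, 120-sample series with clean 4-block community structure."""
    rng = np.random.default_rng(42)
    latents = rng.standard_normal((4, 120))
    init = small_atlas.to_int_labels(list(small_atlas.mapping))
    signals = 0.9 * latents[init - 1] + np.sqrt(1 - 0.81) * rng.standard_normal((16, 120))
    return ParcellatedSeries("toy", signals, 1.0, list(small_atlas.mapping))


@pytest.fixture
def modular_weights():
    """Perfectly modular 6-node weights: two 3-cliques, no cross edges."""
    w = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    return w
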