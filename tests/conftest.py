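import numpy as np
import pytest
from hypothesis import settings

import moeadm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def karate():
    return moeadm.karate_fixture()


@pytest.fixture(scope="session")
def karate_net(karate):
    return karate[0]


@pytest.fixture()
def bridge():
    """Two triangles joined by a bridge, with the natural split."""
    return moeadm.two_triangles_bridge()


@pytest.fixture()
def triangle():
    return moeadm.Network.from_edges(3, [(0, 1), (0, 2), (1, 2)])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_graph_and_partition(rng, max_nodes=10):
    """A random simple graph plus a random (possibly disconnected-community)
    partition — helper shared by objective-identity tests."""
    n = int(rng.integers(2, max_nodes + 1))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    mask = rng.random(len(pairs)) < 0.4
    edges = [p for p, keep in zip(pairs, mask) if keep]
    if not edges:
        edges = [(0, 1)]
    net = moeadm.Network.from_edges(n, edges)
    k = int(rng.integers(1, n + 1))
    labels = rng.integers(k, size=n)
    return net, moeadm.Partition.from_labels(labels)
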