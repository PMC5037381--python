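"""Benchmark fixtures, planted-partition generator, agreement metrics and the
exhaustive small-graph oracle used to anchor testing.

Everything here runs offline: the Zachary karate-club network ships with the
package as a plain edge list, and all other test networks are generated
programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from sklearn.metrics import normalized_mutual_info_score

from .graph_io import Network, Partition, read_edge_list
from .objectives import modularity_density, modularity_q

__all__ = [
    "karate_fixture",
    "PlantedPartitionSpec",
    "generate_planted_partition",
    "nmi",
    "exhaustive_best_partition",
    "two_triangles_bridge",
]


def karate_fixture() -> tuple[Network, Partition]:
    """The Zachary karate club (34 nodes, 78 edges) and its two-faction split.

    The classic social network of friendships in a university karate club
    that later fissioned into two groups around the instructor and the
    administrator; the returned partition is that observed two-faction
    outcome.
    """
    data = resources.files("moeadm") / "data"
    with resources.as_file(data / "karate.edgelist") as p:
        net = read_edge_list(p)
    truth_text = (data / "karate.truth").read_text()
    labels = {}
    for line in truth_text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        node, comm = line.split()
        labels[int(node)] = int(comm)
    truth = Partition.from_labels([labels[i] for i in range(net.n_nodes)])
    return net, truth


def two_triangles_bridge() -> tuple[Network, Partition]:
    """Two triangles joined by a single bridge edge; natural split attached.

    A 6-node graph whose maximum-modularity clustering (Q = 5/14) is the two
    triangles — handy as a tiny analytically solvable instance.
    """
    edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
    net = Network.from_edges(6, edges)
    return net, Partition.from_labels([0, 0, 0, 1, 1, 1])


@dataclass(frozen=True)
class PlantedPartitionSpec:
    """Planted l-partition model: equal-sized communities with dense
    within-community (``p_in``) and sparse between-community (``p_out``)
    Bernoulli edges.  Recoverable structure needs ``p_in > p_out``."""

    n_communities: int
    community_size: int
    p_in: float
    p_out: float
    seed: int | None = None

    def validate(self) -> None:
        if self.n_communities < 1 or self.community_size < 1:
            raise ValueError("community counts and sizes must be positive")
        if not (0.0 <= self.p_in <= 1.0 and 0.0 <= self.p_out <= 1.0):
            raise ValueError("edge probabilities must lie in [0, 1]")


def generate_planted_partition(
    spec: PlantedPartitionSpec,
) -> tuple[Network, Partition]:
    """Sample a planted-partition graph and return it with the planted truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_communities * spec.community_size
    labels = np.repeat(np.arange(spec.n_communities), spec.community_size)
    edges: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            p = spec.p_in if labels[i] == labels[j] else spec.p_out
            if rng.random() < p:
                edges.append((i, j))
    return Network.from_edges(n, edges), Partition.from_labels(labels)


def nmi(p: Partition, q: Partition) -> float:
    """Normalized mutual information (arithmetic normalization) in [0, 1].

    Relabeling-invariant: 1 iff the partitions are identical up to community
    renaming.
    """
    if p.n_nodes != q.n_nodes:
        raise ValueError("partitions must cover the same node set")
    return float(
        normalized_mutual_info_score(
            p.assignment, q.assignment, average_method="arithmetic"
        )
    )


def _set_partitions(n: int):
    """Iterate over all set partitions of range(n) as restricted-growth label lists."""
    labels = [0] * n
    maxes = [0] * n
    while True:
        yield list(labels)
        # next restricted growth string
        i = n - 1
        while i > 0 and labels[i] == maxes[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        labels[i] += 1
        maxes[i] = max(maxes[i - 1], labels[i])
        for j in range(i + 1, n):
            labels[j] = 0
            maxes[j] = maxes[i]


def exhaustive_best_partition(
    net: Network, objective: str = "q", max_nodes: int = 12
) -> tuple[Partition, float]:
    """Enumerate every set partition and return the objective-maximal one.

    Guarded to small graphs (the Bell number explodes); ties are broken in
    favour of fewer communities, then enumeration order.  Intended purely as
    a testing oracle.
    """
    if net.n_nodes > max_nodes:
        raise ValueError(
            f"refusing to enumerate partitions of {net.n_nodes} nodes "
            f"(limit {max_nodes}); the Bell number is astronomically large"
        )
    score = modularity_q if objective == "q" else modularity_density
    if objective not in ("q", "d"):
        raise ValueError("objective must be 'q' or 'd'")
    best_part: Partition | None = None
    best_val = -np.inf
    for labels in _set_partitions(net.n_nodes):
        part = Partition.from_labels(labels)
        val = score(net, part)
        if val > best_val or (
            val == best_val
            and best_part is not None
            and part.n_communities < best_part.n_communities
        ):
            best_part, best_val = part, val
    assert best_part is not None
    return best_part, float(best_val)
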