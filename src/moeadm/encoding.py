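"""Locus-based adjacency encoding of community structure.

A genotype is an integer array with one allele per node; ``allele[i] = j``
asserts that nodes *i* and *j* belong to the same community.  Decoding finds
the connected components of the auxiliary graph ``{(i, allele[i])}``, so the
number of communities is determined automatically rather than fixed up front.
Alleles are restricted to graph neighbours (isolated nodes point at
themselves), which guarantees every decoded community induces a connected
subgraph and keeps the search space to genuinely realizable clusterings.
"""

from __future__ import annotations

import numpy as np

from .graph_io import Network, Partition

__all__ = [
    "random_genotype",
    "decode",
    "encode_partition",
    "two_point_crossover",
    "mutate",
]


def _validate(genotype: np.ndarray, net: Network) -> np.ndarray:
    g = np.asarray(genotype, dtype=np.int64)
    if g.shape != (net.n_nodes,):
        raise ValueError("genotype length must equal the number of nodes")
    if g.size and (g.min() < 0 or g.max() >= net.n_nodes):
        raise ValueError("allele out of node-index range")
    return g


def random_genotype(net: Network, rng: np.random.Generator) -> np.ndarray:
    """Draw each allele uniformly from the node's neighbours (self if isolated)."""
    alleles = np.arange(net.n_nodes, dtype=np.int64)
    for i in range(net.n_nodes):
        nbrs = net.neighbors(i)
        if nbrs.size:
            alleles[i] = nbrs[rng.integers(nbrs.size)]
    return alleles


def decode(genotype: np.ndarray, net: Network) -> Partition:
    """Connected components of the allele graph, labelled by first appearance."""
    g = _validate(genotype, net)
    n = net.n_nodes
    parent = list(range(n))

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    for i, j in enumerate(g.tolist()):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    return Partition.from_labels([find(i) for i in range(n)])


def encode_partition(
    partition: Partition, net: Network, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Inverse of :func:`decode` up to components: spanning-tree parent pointers.

    Each community must induce a connected subgraph of ``net``; a BFS tree is
    built per community, every node's allele is its tree parent and the root
    points at itself.  ``decode(encode_partition(p)) == p`` always.
    """
    if partition.assignment.size != net.n_nodes:
        raise ValueError("partition does not match network size")
    labels = partition.assignment
    alleles = np.arange(net.n_nodes, dtype=np.int64)
    for members in partition.communities():
        members_set = set(members.tolist())
        root = int(members[0])
        seen = {root}
        frontier = [root]
        while frontier:
            node = frontier.pop()
            for nbr in net.neighbors(node).tolist():
                if nbr in members_set and nbr not in seen:
                    alleles[nbr] = node
                    seen.add(nbr)
                    frontier.append(nbr)
        if len(seen) != len(members_set):
            raise ValueError(
                f"community {int(labels[root])} does not induce a connected subgraph"
            )
    return alleles


def two_point_crossover(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exchange the allele segment between two cut points i <= j (inclusive).

    The points are drawn uniformly with replacement and ordered, so a
    single-locus swap (i == j) is possible.  At every locus each child's
    allele comes from one of the two parents.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    n = a.size
    i, j = sorted(rng.integers(0, n, size=2).tolist())
    child1, child2 = a.copy(), b.copy()
    child1[i : j + 1] = b[i : j + 1]
    child2[i : j + 1] = a[i : j + 1]
    return child1, child2


def mutate(
    genotype: np.ndarray, net: Network, pm: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-locus neighbour re-draw: with probability ``pm`` each allele is
    replaced by a uniform draw from that node's neighbours (self if isolated)."""
    if not 0.0 <= pm <= 1.0:
        raise ValueError("mutation probability must lie in [0, 1]")
    g = _validate(genotype, net).copy()
    if pm == 0.0:
        return g
    hits = np.flatnonzero(rng.random(g.size) < pm)
    for i in hits.tolist():
        nbrs = net.neighbors(i)
        g[i] = nbrs[rng.integers(nbrs.size)] if nbrs.size else i
    return g
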