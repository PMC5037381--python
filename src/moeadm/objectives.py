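"""Community-quality objectives, Pareto dominance and Tchebycheff scalarization.

The optimizer minimizes the pair (NRA, RC):

* NRA, negative ratio association: ``-sum_s L(S_s, S_s) / |S_s|`` — the
  (negated) within-community link density, where ``L(A, A)`` counts each
  internal edge twice.
* RC, ratio cut: ``sum_s L(S_s, ~S_s) / |S_s|`` — cross-community link
  density.

Their negated sum is the modularity density
``D = sum_s (L(S_s, S_s) - L(S_s, ~S_s)) / |S_s| = -(NRA + RC)``, an exact
algebraic identity under the double-count convention.  The Newman–Girvan
modularity Q is computed only for reporting and final model selection.
"""

from __future__ import annotations

import numpy as np

from .graph_io import Network, Partition

__all__ = [
    "community_link_counts",
    "nra",
    "rc",
    "evaluate",
    "modularity_density",
    "modularity_q",
    "dominates",
    "tchebycheff",
    "update_reference",
]


def community_link_counts(
    net: Network, partition: Partition
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-community (size, internal L(S,S), external L(S,~S)) arrays.

    Internal counts include both orientations of each within-community edge.
    """
    labels = partition.assignment
    if labels.size != net.n_nodes:
        raise ValueError("partition does not match network size")
    k = partition.n_communities
    sizes = np.bincount(labels, minlength=k).astype(np.float64)
    if np.any(sizes == 0):
        raise ValueError("empty community in partition")
    lu, lv = labels[net.edge_u], labels[net.edge_v]
    same = lu == lv
    w = net.weights
    internal = 2.0 * np.bincount(lu[same], weights=w[same], minlength=k)
    external = np.bincount(lu[~same], weights=w[~same], minlength=k) + np.bincount(
        lv[~same], weights=w[~same], minlength=k
    )
    return sizes, internal, external


def nra(net: Network, partition: Partition) -> float:
    """Negative ratio association (to minimize); always <= 0."""
    sizes, internal, _ = community_link_counts(net, partition)
    return float(-(internal / sizes).sum())


def rc(net: Network, partition: Partition) -> float:
    """Ratio cut (to minimize); always >= 0."""
    sizes, _, external = community_link_counts(net, partition)
    return float((external / sizes).sum())


def evaluate(net: Network, partition: Partition) -> tuple[float, float]:
    """The (NRA, RC) objective vector in one pass over the edges."""
    sizes, internal, external = community_link_counts(net, partition)
    return float(-(internal / sizes).sum()), float((external / sizes).sum())


def modularity_density(net: Network, partition: Partition) -> float:
    """Modularity density D = sum_s (internal - external degree) / size.

    Identically equal to ``-(nra + rc)``.
    """
    sizes, internal, external = community_link_counts(net, partition)
    return float(((internal - external) / sizes).sum())


def modularity_q(net: Network, partition: Partition) -> float:
    """Newman–Girvan modularity Q.

    ``Q = sum_s [ l_s / M - (d_s / 2M)^2 ]`` with ``l_s`` the internal edge
    weight of community *s*, ``d_s`` its total degree and ``M`` the total edge
    weight.  Zero for the single-community partition; always < 1.
    """
    if net.n_edges == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    sizes, internal, external = community_link_counts(net, partition)
    m = float(net.weights.sum())
    l_s = internal / 2.0
    d_s = internal + external
    return float((l_s / m - (d_s / (2.0 * m)) ** 2).sum())


def dominates(u: tuple[float, float], v: tuple[float, float]) -> bool:
    """Pareto dominance for minimization: u <= v everywhere, < somewhere."""
    return all(ui <= vi for ui, vi in zip(u, v)) and any(
        ui < vi for ui, vi in zip(u, v)
    )


def tchebycheff(
    f: tuple[float, float],
    w: tuple[float, float],
    z: tuple[float, float],
) -> float:
    """Weighted Tchebycheff scalarization ``max_i w_i |f_i - z_i|``.

    The absolute value keeps the terms nonnegative even if the reference
    point *z* is later improved past a stored objective value.
    """
    if abs(sum(w) - 1.0) > 1e-9 or any(wi < 0 for wi in w):
        raise ValueError("weights must be nonnegative and sum to 1")
    return max(wi * abs(fi - zi) for wi, fi, zi in zip(w, f, z))


def update_reference(
    z: tuple[float, float], f: tuple[float, float]
) -> tuple[float, float]:
    """Component-wise minimum of the running reference point and a new vector."""
    return tuple(min(zi, fi) for zi, fi in zip(z, f))  # type: ignore[return-value]
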