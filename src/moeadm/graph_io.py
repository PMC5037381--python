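"""Network and partition containers plus readers/writers for standard graph formats.

The in-memory :class:`Network` is a thin immutable view of a simple undirected
graph: contiguous 0-based node indices, a canonical edge array, optional
positive weights and optional external node labels.  All community-quality
objectives are expressed in terms of the link-count primitive
:func:`link_count` (``L(A, B)``), defined here so that every module shares one
counting convention: when ``A == B`` each internal edge is counted twice
(both orientations), which is the convention of the modularity-density
literature and makes ``D = -(NRA + RC)`` an exact identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "Partition",
    "read_edge_list",
    "read_gml",
    "read_pajek",
    "link_count",
    "internal_external_degree",
    "community_strength",
    "write_partition",
    "read_partition",
]


class GraphParseError(ValueError):
    """Raised when an input file cannot be parsed as a graph."""


@dataclass(frozen=True)
class Network:
    """Simple undirected graph with 0-based contiguous node indices.

    Parameters
    ----------
    n_nodes : int
        Number of nodes; valid indices are ``0 .. n_nodes - 1``.
    edge_u, edge_v : ndarray of int
        Endpoint arrays, one entry per edge, canonicalized so that
        ``edge_u[k] < edge_v[k]``.  No self-loops, no duplicates.
    weights : ndarray of float
        Positive weight per edge (all 1 for unweighted graphs).
    labels : tuple of str, optional
        External node names, index-aligned; defaults to stringified indices.
    """

    n_nodes: int
    edge_u: np.ndarray
    edge_v: np.ndarray
    weights: np.ndarray
    labels: tuple[str, ...] | None = None
    _adjacency: list[np.ndarray] = field(default=None, repr=False, compare=False)
    _degrees: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        u = np.asarray(self.edge_u, dtype=np.int64)
        v = np.asarray(self.edge_v, dtype=np.int64)
        w = np.asarray(self.weights, dtype=np.float64)
        if u.shape != v.shape or u.shape != w.shape:
            raise ValueError("edge arrays must have identical length")
        if u.size and (u.min() < 0 or v.max() >= self.n_nodes):
            raise ValueError("edge endpoint out of range")
        if np.any(u == v):
            raise ValueError("self-loops are not allowed")
        if np.any(w <= 0):
            raise ValueError("edge weights must be positive")
        lo, hi = np.minimum(u, v), np.maximum(u, v)
        order = np.lexsort((hi, lo))
        lo, hi, w = lo[order], hi[order], w[order]
        if lo.size > 1:
            dup = (lo[1:] == lo[:-1]) & (hi[1:] == hi[:-1])
            if np.any(dup):
                raise ValueError("duplicate edges are not allowed")
        object.__setattr__(self, "edge_u", lo)
        object.__setattr__(self, "edge_v", hi)
        object.__setattr__(self, "weights", w)
        if self.labels is not None and len(self.labels) != self.n_nodes:
            raise ValueError("labels must be index-aligned with nodes")
        # adjacency lists and degrees, built eagerly (used in every genotype op)
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for a, b in zip(lo.tolist(), hi.tolist()):
            adj[a].append(b)
            adj[b].append(a)
        object.__setattr__(
            self, "_adjacency", [np.array(nbrs, dtype=np.int64) for nbrs in adj]
        )
        deg = np.zeros(self.n_nodes, dtype=np.float64)
        np.add.at(deg, lo, w)
        np.add.at(deg, hi, w)
        object.__setattr__(self, "_degrees", deg)

    @property
    def n_edges(self) -> int:
        return int(self.edge_u.size)

    @property
    def is_weighted(self) -> bool:
        return bool(np.any(self.weights != 1.0))

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree of every node; sums to ``2 * n_edges`` when unweighted."""
        return self._degrees

    def neighbors(self, i: int) -> np.ndarray:
        if not 0 <= i < self.n_nodes:
            raise IndexError(f"node index {i} out of range")
        return self._adjacency[i]

    @property
    def edge_set(self) -> set[tuple[int, int]]:
        return set(zip(self.edge_u.tolist(), self.edge_v.tolist()))

    def label_of(self, i: int) -> str:
        return self.labels[i] if self.labels is not None else str(i)

    @classmethod
    def from_edges(
        cls,
        n_nodes: int,
        edges: Iterable[tuple[int, int]],
        weights: Sequence[float] | None = None,
        labels: Sequence[str] | None = None,
    ) -> "Network":
        edges = list(edges)
        u = np.array([e[0] for e in edges], dtype=np.int64)
        v = np.array([e[1] for e in edges], dtype=np.int64)
        w = (
            np.ones(len(edges), dtype=np.float64)
            if weights is None
            else np.asarray(weights, dtype=np.float64)
        )
        return cls(n_nodes, u, v, w, tuple(labels) if labels is not None else None)

    @classmethod
    def from_networkx(cls, graph: nx.Graph) -> "Network":
        """Convert an undirected networkx graph, remapping ids to 0-based indices.

        Self-loops are dropped and (for multigraphs) parallel edges collapsed
        keeping the maximum weight, with a logged warning.
        """
        if graph.is_directed():
            raise ValueError("directed graphs are not supported")
        nodes = list(graph.nodes())
        index = {node: i for i, node in enumerate(nodes)}
        best: dict[tuple[int, int], float] = {}
        dropped_loops = 0
        for a, b, data in graph.edges(data=True):
            if a == b:
                dropped_loops += 1
                continue
            i, j = index[a], index[b]
            key = (min(i, j), max(i, j))
            w = float(data.get("weight", 1.0))
            if key not in best or w > best[key]:
                best[key] = w
        if dropped_loops:
            logger.warning("dropped %d self-loop(s)", dropped_loops)
        keys = sorted(best)
        return cls(
            len(nodes),
            np.array([k[0] for k in keys], dtype=np.int64),
            np.array([k[1] for k in keys], dtype=np.int64),
            np.array([best[k] for k in keys], dtype=np.float64),
            tuple(str(node) for node in nodes),
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for a, b, w in zip(self.edge_u.tolist(), self.edge_v.tolist(), self.weights):
            g.add_edge(a, b, weight=float(w))
        return g


@dataclass(frozen=True)
class Partition:
    """Node-to-community assignment with canonical (first-appearance) labels."""

    assignment: np.ndarray
    n_communities: int

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "Partition":
        """Build a canonical partition: community ids relabeled by first appearance."""
        arr = np.asarray(labels)
        if arr.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        canon = np.empty(arr.size, dtype=np.int64)
        mapping: dict = {}
        for i, lab in enumerate(arr.tolist()):
            if lab not in mapping:
                mapping[lab] = len(mapping)
            canon[i] = mapping[lab]
        return cls(canon, len(mapping))

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=np.int64)
        object.__setattr__(self, "assignment", a)

    @property
    def n_nodes(self) -> int:
        return int(self.assignment.size)

    def communities(self) -> list[np.ndarray]:
        """Node-index arrays, one per community, in canonical label order."""
        order = np.argsort(self.assignment, kind="stable")
        sorted_labels = self.assignment[order]
        cuts = np.searchsorted(sorted_labels, np.arange(1, self.n_communities))
        return np.split(order, cuts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.n_communities == other.n_communities and np.array_equal(
            self.assignment, other.assignment
        )

    def __hash__(self) -> int:
        return hash((self.n_communities, self.assignment.tobytes()))


# ---------------------------------------------------------------------------
# readers


def _finalize_edges(
    raw_edges: list[tuple[str, str, float]],
    declared_nodes: Sequence[str] | None = None,
) -> Network:
    """Remap raw labeled edges to 0-based indices, collapsing dups, dropping loops."""
    labels: list[str] = list(declared_nodes) if declared_nodes else []
    index: dict[str, int] = {lab: i for i, lab in enumerate(labels)}
    for a, b, _ in raw_edges:
        for lab in (a, b):
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)
    best: dict[tuple[int, int], float] = {}
    dropped_loops = dropped_dups = 0
    for a, b, w in raw_edges:
        i, j = index[a], index[b]
        if i == j:
            dropped_loops += 1
            continue
        key = (min(i, j), max(i, j))
        if key in best:
            dropped_dups += 1
            best[key] = max(best[key], w)
        else:
            best[key] = w
    if dropped_loops or dropped_dups:
        logger.warning(
            "collapsed %d duplicate edge(s), dropped %d self-loop(s)",
            dropped_dups,
            dropped_loops,
        )
    keys = sorted(best)
    return Network(
        len(labels),
        np.array([k[0] for k in keys], dtype=np.int64),
        np.array([k[1] for k in keys], dtype=np.int64),
        np.array([best[k] for k in keys], dtype=np.float64),
        tuple(labels),
    )


def read_edge_list(
    path: str | Path,
    delimiter: str | None = None,
    indexing: str = "zero",
) -> Network:
    """Read a plain edge list (2 or 3 whitespace/``delimiter``-separated tokens).

    Lines starting with ``#`` (or ``%``) and blank lines are skipped.  Node
    ids are remapped to 0-based contiguous indices; the original ids are kept
    as labels.  Duplicate edges are collapsed (max weight kept) and self-loops
    dropped, with a logged count.

    Parameters
    ----------
    delimiter : str, optional
        Token separator; ``None`` splits on any whitespace (and commas).
    indexing : {"zero", "one"}
        Only affects the *labels* kept for output; internal indices are
        always assigned by first appearance.
    """
    if indexing not in ("zero", "one"):
        raise ValueError("indexing must be 'zero' or 'one'")
    path = Path(path)
    raw: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "%")):
                continue
            if delimiter is None:
                tokens = stripped.replace(",", " ").split()
            else:
                tokens = [t.strip() for t in stripped.split(delimiter)]
            if len(tokens) not in (2, 3):
                raise GraphParseError(
                    f"{path.name}:{lineno}: expected 2 or 3 tokens, got {len(tokens)}"
                )
            w = 1.0
            if len(tokens) == 3:
                try:
                    w = float(tokens[2])
                except ValueError as exc:
                    raise GraphParseError(
                        f"{path.name}:{lineno}: bad weight {tokens[2]!r}"
                    ) from exc
                if w <= 0:
                    raise GraphParseError(
                        f"{path.name}:{lineno}: weight must be positive, got {w}"
                    )
            raw.append((tokens[0], tokens[1], w))
    return _finalize_edges(raw)


def read_gml(path: str | Path) -> Network:
    """Read a GML file (``node [ id ... ]`` / ``edge [ source ... target ... ]``)."""
    try:
        graph = nx.read_gml(Path(path), label="id")
    except Exception as exc:  # networkx raises several parser exception types
        raise GraphParseError(f"cannot parse GML file {path}: {exc}") from exc
    return Network.from_networkx(nx.Graph(graph))


def read_pajek(path: str | Path) -> Network:
    """Read a Pajek ``.net`` file; 1-based vertex ids become 0-based indices.

    Isolated vertices declared in ``*Vertices`` are preserved.
    """
    try:
        graph = nx.read_pajek(Path(path))
    except Exception as exc:
        raise GraphParseError(f"cannot parse Pajek file {path}: {exc}") from exc
    return Network.from_networkx(nx.Graph(graph))


# ---------------------------------------------------------------------------
# link-count primitives


def _as_mask(net: Network, nodes: Iterable[int]) -> np.ndarray:
    mask = np.zeros(net.n_nodes, dtype=bool)
    idx = np.asarray(list(nodes), dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= net.n_nodes):
        raise IndexError("node index out of range")
    mask[idx] = True
    return mask


def link_count(net: Network, a: Iterable[int], b: Iterable[int]) -> float:
    """L(A, B) = sum over ordered pairs (i in A, j in B) of the adjacency weight.

    Both orientations of every edge are considered, so ``L(A, A)`` counts each
    internal edge twice — the convention under which the modularity density
    decomposes exactly into ratio-association and ratio-cut terms.
    """
    ma, mb = _as_mask(net, a), _as_mask(net, b)
    u, v, w = net.edge_u, net.edge_v, net.weights
    total = w[ma[u] & mb[v]].sum() + w[ma[v] & mb[u]].sum()
    return float(total)


def internal_external_degree(
    net: Network, partition: Partition, i: int
) -> tuple[float, float]:
    """Split node *i*'s degree into within-community and cross-community parts.

    Satisfies ``k_in + k_out == degree(i)`` for every node and partition.
    """
    if not 0 <= i < net.n_nodes:
        raise IndexError(f"node index {i} out of range")
    if partition.assignment.size != net.n_nodes:
        raise ValueError("partition does not match network size")
    u, v, w = net.edge_u, net.edge_v, net.weights
    labels = partition.assignment
    incident_u = u == i
    incident_v = v == i
    same_u = labels[v[incident_u]] == labels[i]
    same_v = labels[u[incident_v]] == labels[i]
    k_in = w[incident_u][same_u].sum() + w[incident_v][same_v].sum()
    k_out = w[incident_u][~same_u].sum() + w[incident_v][~same_v].sum()
    return float(k_in), float(k_out)


def community_strength(net: Network, partition: Partition) -> list[str]:
    """Classify each community as ``strong``, ``weak`` or ``neither``.

    A community is *strong* when every member has more internal than external
    links, *weak* when the totals satisfy that inequality, and *neither*
    otherwise.  Diagnostic only; not used by the optimizer.
    """
    if partition.assignment.size != net.n_nodes:
        raise ValueError("partition does not match network size")
    counts = np.bincount(partition.assignment, minlength=partition.n_communities)
    if np.any(counts == 0):
        raise ValueError("empty community in partition")
    labels = partition.assignment
    u, v, w = net.edge_u, net.edge_v, net.weights
    k_in = np.zeros(net.n_nodes)
    same = labels[u] == labels[v]
    np.add.at(k_in, u[same], w[same])
    np.add.at(k_in, v[same], w[same])
    k_out = net.degrees - k_in
    out: list[str] = []
    for members in partition.communities():
        if np.all(k_in[members] > k_out[members]):
            out.append("strong")
        elif k_in[members].sum() > k_out[members].sum():
            out.append("weak")
        else:
            out.append("neither")
    return out


# ---------------------------------------------------------------------------
# partition I/O


def write_partition(
    partition: Partition,
    net: Network,
    path: str | Path,
    format: str = "two-column",
) -> None:
    """Write a partition as ``label community`` pairs or a Pajek ``.clu`` file."""
    if partition.assignment.size != net.n_nodes:
        raise ValueError("partition does not match network size")
    path = Path(path)
    lines: list[str] = []
    if format == "two-column":
        for i, c in enumerate(partition.assignment.tolist()):
            lines.append(f"{net.label_of(i)}\t{c}")
    elif format == "clu":
        lines.append(f"*Vertices {net.n_nodes}")
        # Pajek cluster ids are 1-based
        lines.extend(str(c + 1) for c in partition.assignment.tolist())
    else:
        raise ValueError(f"unknown partition format {format!r}")
    path.write_text("\n".join(lines) + "\n")


def read_partition(path: str | Path, net: Network | None = None) -> Partition:
    """Read a partition written by :func:`write_partition` (either format)."""
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.strip().startswith(("#", "%"))
    ]
    if not lines:
        raise GraphParseError(f"{path.name}: empty partition file")
    if lines[0].lower().startswith("*vertices"):
        labels = [int(ln) for ln in lines[1:]]
        return Partition.from_labels(labels)
    by_label: dict[str, int] = {}
    for ln in lines:
        tokens = ln.split()
        if len(tokens) != 2:
            raise GraphParseError(f"{path.name}: expected 2 tokens per line")
        by_label[tokens[0]] = int(tokens[1])
    if net is not None:
        labels = [by_label[net.label_of(i)] for i in range(net.n_nodes)]
    else:
        labels = [by_label[k] for k in by_label]
    return Partition.from_labels(labels)
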