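"""Scikit-learn-style estimator facade over the evolutionary optimizer.

``MOEADM`` (membrane-partitioned population) and ``MOEAD`` (classic
decomposition baseline) are clusterers in the sklearn idiom: construct with
hyper-parameters, ``fit`` on a graph, read ``labels_`` / ``modularity_``.
They accept a :class:`~moeadm.graph_io.Network`, a ``networkx.Graph`` or an
edge array of shape (m, 2).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .graph_io import Network
from .moea_dm import AlgorithmConfig, run, run_moead_baseline

__all__ = ["MOEADM", "MOEAD", "as_network"]


def as_network(X) -> Network:
    """Coerce estimator input (Network, networkx graph, or edge array) to Network."""
    if isinstance(X, Network):
        return X
    try:
        import networkx as nx

        if isinstance(X, nx.Graph):
            return Network.from_networkx(X)
    except ImportError:  # pragma: no cover
        pass
    arr = np.asarray(X)
    if arr.ndim == 2 and arr.shape[1] == 2:
        n = int(arr.max()) + 1 if arr.size else 0
        return Network.from_edges(n, [tuple(e) for e in arr.tolist()])
    raise TypeError(
        "expected a Network, an undirected networkx graph, or an (m, 2) edge array"
    )


class _BaseMOEA(ClusterMixin, BaseEstimator):
    """Shared fit machinery; subclasses define the config and engine."""

    def _config(self) -> AlgorithmConfig:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y=None):
        """Cluster the graph ``X``; ``y`` is ignored (unsupervised)."""
        net = as_network(X)
        config = self._config()
        result = (
            run_moead_baseline(net, config)
            if config.mode == "moea_d"
            else run(net, config)
        )
        self.n_features_in_ = net.n_nodes
        self.labels_ = result.best_partition.assignment.copy()
        self.n_communities_ = result.best_partition.n_communities
        self.modularity_ = result.best_q
        self.best_partition_ = result.best_partition
        self.archive_ = result.archive
        self.history_ = result.history
        self.reference_point_ = (result.history[-1].z1, result.history[-1].z2) if result.history else None
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class MOEADM(_BaseMOEA):
    """Membrane-structured decomposition-based evolutionary community detector.

    The population is split evenly over ``cell_num`` membranes, one per
    Tchebycheff subproblem; membranes evolve locally and exchange their best
    solutions along the weight-vector chain each generation.  The fitted
    ``labels_`` are the archive clustering with maximal modularity Q.

    Parameters
    ----------
    popsize : int, default 120
        Total population; must be divisible by ``cell_num``.
    cell_num : int, default 40
        Number of membranes (= scalar subproblems).
    niche : int, default 13
        Neighbourhood size used when picking a mate's membrane.
    pc, pm : float
        Crossover probability (default 1.0) and per-locus mutation rate
        (default 0.06).
    maxgen : int, default 200
        Number of generations.
    adjacency : {"chain", "ring"}
        Membrane migration topology.
    random_state : int, optional
        Seed; identical seeds give byte-identical histories.
    """

    def __init__(
        self,
        popsize: int = 120,
        cell_num: int = 40,
        niche: int = 13,
        pc: float = 1.0,
        pm: float = 0.06,
        maxgen: int = 200,
        adjacency: str = "chain",
        random_state: int | None = None,
    ):
        self.popsize = popsize
        self.cell_num = cell_num
        self.niche = niche
        self.pc = pc
        self.pm = pm
        self.maxgen = maxgen
        self.adjacency = adjacency
        self.random_state = random_state

    def _config(self) -> AlgorithmConfig:
        return AlgorithmConfig(
            popsize=self.popsize,
            cell_num=self.cell_num,
            niche=self.niche,
            pc=self.pc,
            pm=self.pm,
            maxgen=self.maxgen,
            seed=self.random_state,
            mode="moea_dm",
            adjacency=self.adjacency,
        )


class MOEAD(_BaseMOEA):
    """Classic decomposition-based evolutionary community detector (baseline).

    One solution per subproblem, mating and replacement confined to a
    ``niche``-sized neighbourhood of weight vectors.  Defaults follow the
    conventional baseline settings (popsize 100, niche 40).
    """

    def __init__(
        self,
        popsize: int = 100,
        niche: int = 40,
        pc: float = 1.0,
        pm: float = 0.06,
        maxgen: int = 200,
        random_state: int | None = None,
    ):
        self.popsize = popsize
        self.niche = niche
        self.pc = pc
        self.pm = pm
        self.maxgen = maxgen
        self.random_state = random_state

    def _config(self) -> AlgorithmConfig:
        return AlgorithmConfig(
            popsize=self.popsize,
            cell_num=1,
            niche=self.niche,
            pc=self.pc,
            pm=self.pm,
            maxgen=self.maxgen,
            seed=self.random_state,
            mode="moea_d",
        )
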