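"""Decomposition-based multi-objective evolutionary optimizer with a
membrane-partitioned population (MOEA/DM), plus a classic MOEA/D baseline.

The bi-objective problem min (NRA, RC) is decomposed into ``cell_num``
scalar subproblems via uniformly spread weight vectors and the Tchebycheff
scalarization.  Each subproblem owns one *membrane*: a small sub-population of
``popsize / cell_num`` solutions that evolves locally (two-point crossover +
neighbour-redraw mutation, worst-member replacement) and, once per
generation, sends its best solution to the index-adjacent membranes.  A
global Pareto archive collects every evaluated solution; the reported
clustering is the archive entry with maximal Newman–Girvan modularity Q.

The baseline mode is the classic decomposition algorithm: one solution per
subproblem, mating and replacement inside a ``niche``-sized neighbourhood of
subproblems.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .encoding import decode, mutate, random_genotype, two_point_crossover
from .graph_io import Network, Partition
from .objectives import community_link_counts, dominates, tchebycheff

__all__ = [
    "AlgorithmConfig",
    "Subproblem",
    "Membrane",
    "ArchiveEntry",
    "Archive",
    "GenerationRecord",
    "RunResult",
    "generate_weights",
    "build_membranes",
    "evolve_membrane",
    "migrate",
    "update_archive",
    "run",
    "run_moead_baseline",
    "history_to_csv",
]


@dataclass(frozen=True)
class AlgorithmConfig:
    """Run parameters.

    Defaults are the membrane algorithm's standard settings: population 120
    split over 40 membranes (3 solutions each), neighbourhood size 13,
    certain crossover (pc = 1), per-locus mutation rate 0.06, 200
    generations.  The baseline mode conventionally uses ``popsize=100``,
    ``niche=40`` with ``cell_num`` ignored.
    """

    popsize: int = 120
    cell_num: int = 40
    niche: int = 13
    pc: float = 1.0
    pm: float = 0.06
    maxgen: int = 200
    seed: int | None = None
    mode: str = "moea_dm"
    adjacency: str = "chain"  # membrane topology: "chain" or "ring"

    def validate(self) -> None:
        if self.mode not in ("moea_dm", "moea_d"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.adjacency not in ("chain", "ring"):
            raise ValueError(f"unknown adjacency {self.adjacency!r}")
        if self.popsize < 1 or self.maxgen < 0:
            raise ValueError("popsize and maxgen must be positive")
        if not (0.0 <= self.pc <= 1.0 and 0.0 <= self.pm <= 1.0):
            raise ValueError("pc and pm must lie in [0, 1]")
        if self.mode == "moea_dm":
            if self.cell_num < 1 or self.popsize % self.cell_num != 0:
                raise ValueError("popsize must be divisible by cell_num")
            if not 1 <= self.niche <= self.cell_num:
                raise ValueError("niche must lie in [1, cell_num]")
        else:
            if not 1 <= self.niche <= self.popsize:
                raise ValueError("niche must lie in [1, popsize]")


@dataclass(frozen=True)
class Subproblem:
    """One scalar subproblem: a weight vector plus its niche of nearest peers."""

    index: int
    weight: tuple[float, float]
    neighbor_indices: tuple[int, ...]


class _Solution(NamedTuple):
    genotype: np.ndarray
    objectives: tuple[float, float]
    partition: Partition
    q: float


@dataclass
class Membrane:
    """A subproblem's sub-population; size stays constant across generations."""

    subproblem: Subproblem
    solutions: list[_Solution]

    def scalarized(self, z: tuple[float, float]) -> list[float]:
        w = self.subproblem.weight
        return [tchebycheff(s.objectives, w, z) for s in self.solutions]

    def best_index(self, z: tuple[float, float]) -> int:
        vals = self.scalarized(z)
        return min(range(len(vals)), key=vals.__getitem__)

    def worst_index(self, z: tuple[float, float]) -> int:
        vals = self.scalarized(z)
        return max(range(len(vals)), key=vals.__getitem__)

    @property
    def best(self) -> _Solution:
        raise AttributeError("best depends on the reference point; use best_index(z)")


@dataclass
class ArchiveEntry:
    genotype: np.ndarray
    objectives: tuple[float, float]
    partition: Partition
    q: float


@dataclass
class Archive:
    """Mutually non-dominated set of every solution offered to it.

    ``log_candidates=True`` keeps the full insertion stream so tests can
    compare the archive against a brute-force non-dominated filter.
    """

    entries: list[ArchiveEntry] = field(default_factory=list)
    log_candidates: bool = False
    candidate_log: list[tuple[float, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def insert(self, candidate: ArchiveEntry) -> bool:
        if self.log_candidates:
            self.candidate_log.append(candidate.objectives)
        f = candidate.objectives
        survivors: list[ArchiveEntry] = []
        for entry in self.entries:
            g = entry.objectives
            if dominates(g, f):
                return False
            if g == f and entry.partition == candidate.partition:
                return False  # exact duplicate
            if not dominates(f, g):
                survivors.append(entry)
        survivors.append(candidate)
        self.entries = survivors
        return True

    def update(self, candidates: Iterable[ArchiveEntry]) -> None:
        for c in candidates:
            self.insert(c)

    def best_by_q(self) -> ArchiveEntry:
        """Max-Q entry; ties broken by fewer communities, then lower NRA + RC."""
        if not self.entries:
            raise ValueError("archive is empty")
        return min(
            self.entries,
            key=lambda e: (-e.q, e.partition.n_communities, sum(e.objectives)),
        )

    def max_q(self) -> float:
        return max(e.q for e in self.entries) if self.entries else float("nan")


def update_archive(archive: Archive, candidates: Iterable[ArchiveEntry]) -> Archive:
    archive.update(candidates)
    return archive


class GenerationRecord(NamedTuple):
    generation: int
    best_q: float
    z1: float
    z2: float
    archive_size: int


class RunResult(NamedTuple):
    archive: Archive
    best_partition: Partition
    best_q: float
    history: list[GenerationRecord]


def history_to_csv(history: Sequence[GenerationRecord]) -> str:
    lines = ["generation,best_q,z1,z2,archive_size"]
    for rec in history:
        lines.append(
            f"{rec.generation},{rec.best_q!r},{rec.z1!r},{rec.z2!r},{rec.archive_size}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# shared machinery


def _evaluate_solution(genotype: np.ndarray, net: Network) -> _Solution:
    """Decode and score a genotype: (NRA, RC) objectives plus modularity Q."""
    part = decode(genotype, net)
    sizes, internal, external = community_link_counts(net, part)
    f = (float(-(internal / sizes).sum()), float((external / sizes).sum()))
    m = float(net.weights.sum())
    l_s = internal / 2.0
    d_s = internal + external
    q = float((l_s / m - (d_s / (2.0 * m)) ** 2).sum())
    return _Solution(genotype, f, part, q)


def generate_weights(k: int) -> list[tuple[float, float]]:
    """k uniformly spread weight vectors on the 2-simplex, ordered by first component."""
    if k < 1:
        raise ValueError("need at least one weight vector")
    if k == 1:
        return [(0.5, 0.5)]
    return [(i / (k - 1), 1.0 - i / (k - 1)) for i in range(k)]


def _build_subproblems(k: int, niche: int) -> list[Subproblem]:
    weights = np.array(generate_weights(k))
    subs: list[Subproblem] = []
    for i in range(k):
        d = np.linalg.norm(weights - weights[i], axis=1)
        order = np.argsort(d, kind="stable")[:niche]
        subs.append(
            Subproblem(i, (float(weights[i, 0]), float(weights[i, 1])), tuple(int(j) for j in order))
        )
    return subs


def _make_offspring(
    p1: np.ndarray,
    p2: np.ndarray,
    net: Network,
    config: AlgorithmConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    if rng.random() < config.pc:
        c1, c2 = two_point_crossover(p1, p2, rng)
    else:
        c1, c2 = p1.copy(), p2.copy()
    return mutate(c1, net, config.pm, rng), mutate(c2, net, config.pm, rng)


# ---------------------------------------------------------------------------
# membrane algorithm


def build_membranes(
    config: AlgorithmConfig, net: Network, rng: np.random.Generator
) -> tuple[list[Membrane], tuple[float, float]]:
    """Initialize one membrane per subproblem and the global reference point.

    Each membrane is seeded with ``popsize / cell_num`` random neighbour-allele
    genotypes; the reference point starts at the component-wise minimum of the
    whole initial population's objective vectors.
    """
    config.validate()
    if config.popsize % config.cell_num != 0:
        raise ValueError("popsize must be divisible by cell_num")
    per = config.popsize // config.cell_num
    subs = _build_subproblems(config.cell_num, config.niche)
    membranes = [
        Membrane(sub, [_evaluate_solution(random_genotype(net, rng), net) for _ in range(per)])
        for sub in subs
    ]
    objs = [s.objectives for mem in membranes for s in mem.solutions]
    z = (min(f[0] for f in objs), min(f[1] for f in objs))
    return membranes, z


def evolve_membrane(
    membrane: Membrane,
    membranes: Sequence[Membrane],
    net: Network,
    config: AlgorithmConfig,
    z: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[list[_Solution], tuple[float, float]]:
    """One local evolution step: mate, mutate, evaluate, replace the worst.

    One parent is drawn from this membrane, the other from a membrane in the
    subproblem's niche.  Offspring replace the membrane's worst member only
    when strictly better under this membrane's scalarization; membrane size
    never changes.  Returns the evaluated offspring (for archive insertion)
    and the updated reference point.
    """
    sols = membrane.solutions
    p1 = sols[rng.integers(len(sols))].genotype
    mate_mem = membranes[
        membrane.subproblem.neighbor_indices[
            rng.integers(len(membrane.subproblem.neighbor_indices))
        ]
    ]
    p2 = mate_mem.solutions[rng.integers(len(mate_mem.solutions))].genotype
    c1, c2 = _make_offspring(p1, p2, net, config, rng)
    offspring = [_evaluate_solution(c1, net), _evaluate_solution(c2, net)]
    for child in offspring:
        z = (min(z[0], child.objectives[0]), min(z[1], child.objectives[1]))
    w = membrane.subproblem.weight
    for child in sorted(offspring, key=lambda s: tchebycheff(s.objectives, w, z)):
        worst = membrane.worst_index(z)
        if tchebycheff(child.objectives, w, z) < tchebycheff(
            sols[worst].objectives, w, z
        ):
            sols[worst] = child
    return offspring, z


def migrate(
    membranes: Sequence[Membrane],
    z: tuple[float, float],
    adjacency: str = "chain",
) -> None:
    """Copy each membrane's best solution into its index-adjacent membranes.

    Membranes are adjacent when their subproblem indices differ by one (the
    weight vectors are ordered, so adjacent membranes are adjacent in
    objective space); a ring additionally joins the endpoints.  The copy
    replaces the receiver's worst member only when strictly better under the
    receiver's weight, and the sender keeps its original.
    """
    k = len(membranes)
    if k < 2:
        return
    bests = [mem.solutions[mem.best_index(z)] for mem in membranes]
    for i, best in enumerate(bests):
        if adjacency == "ring":
            receivers = [(i - 1) % k, (i + 1) % k]
        else:
            receivers = [j for j in (i - 1, i + 1) if 0 <= j < k]
        for j in receivers:
            receiver = membranes[j]
            w = receiver.subproblem.weight
            incoming = tchebycheff(best.objectives, w, z)
            worst = receiver.worst_index(z)
            if incoming < tchebycheff(receiver.solutions[worst].objectives, w, z):
                receiver.solutions[worst] = _Solution(
                    best.genotype.copy(), best.objectives, best.partition, best.q
                )


def run(
    net: Network, config: AlgorithmConfig, log_candidates: bool = False
) -> RunResult:
    """Run the optimizer and return the archive, the max-Q clustering and a history.

    Dispatches on ``config.mode``; deterministic given ``config.seed``.
    """
    config.validate()
    if net.n_edges == 0:
        raise ValueError("cannot cluster an edgeless network")
    if config.mode == "moea_d":
        return run_moead_baseline(net, config, log_candidates=log_candidates)
    rng = np.random.default_rng(config.seed)
    membranes, z = build_membranes(config, net, rng)
    archive = Archive(log_candidates=log_candidates)
    archive.update(
        ArchiveEntry(s.genotype, s.objectives, s.partition, s.q)
        for mem in membranes
        for s in mem.solutions
    )
    history: list[GenerationRecord] = []
    for gen in range(1, config.maxgen + 1):
        for mem in membranes:
            offspring, z = evolve_membrane(mem, membranes, net, config, z, rng)
            archive.update(
                ArchiveEntry(s.genotype, s.objectives, s.partition, s.q)
                for s in offspring
            )
        migrate(membranes, z, config.adjacency)
        history.append(
            GenerationRecord(gen, archive.max_q(), z[0], z[1], len(archive))
        )
    best = archive.best_by_q()
    return RunResult(archive, best.partition, best.q, history)


# ---------------------------------------------------------------------------
# classic decomposition baseline


def run_moead_baseline(
    net: Network, config: AlgorithmConfig, log_candidates: bool = False
) -> RunResult:
    """Classic MOEA/D: one solution per subproblem, niche-neighbourhood mating
    and replacement by scalarized improvement.  Same result contract as
    :func:`run`."""
    config = replace(config, mode="moea_d")
    config.validate()
    if net.n_edges == 0:
        raise ValueError("cannot cluster an edgeless network")
    rng = np.random.default_rng(config.seed)
    subs = _build_subproblems(config.popsize, config.niche)
    weights = np.array([s.weight for s in subs])  # (k, 2)
    pop = [_evaluate_solution(random_genotype(net, rng), net) for _ in subs]
    objs = np.array([s.objectives for s in pop])  # (k, 2)
    z = objs.min(axis=0)
    archive = Archive(log_candidates=log_candidates)
    archive.update(
        ArchiveEntry(s.genotype, s.objectives, s.partition, s.q) for s in pop
    )
    history: list[GenerationRecord] = []
    for gen in range(1, config.maxgen + 1):
        for sub in subs:
            nbrs = sub.neighbor_indices
            i1, i2 = rng.integers(len(nbrs), size=2)
            c1, c2 = _make_offspring(
                pop[nbrs[i1]].genotype, pop[nbrs[i2]].genotype, net, config, rng
            )
            for child_g in (c1, c2):
                child = _evaluate_solution(child_g, net)
                f = np.array(child.objectives)
                z = np.minimum(z, f)
                # vectorized neighbour replacement under each neighbour's weight
                nbr_idx = np.array(nbrs)
                g_child = (weights[nbr_idx] * np.abs(f - z)).max(axis=1)
                g_old = (
                    weights[nbr_idx] * np.abs(objs[nbr_idx] - z)
                ).max(axis=1)
                for pos, j in enumerate(nbr_idx.tolist()):
                    if g_child[pos] < g_old[pos]:
                        pop[j] = child
                        objs[j] = f
                archive.insert(
                    ArchiveEntry(child.genotype, child.objectives, child.partition, child.q)
                )
        history.append(
            GenerationRecord(gen, archive.max_q(), float(z[0]), float(z[1]), len(archive))
        )
    best = archive.best_by_q()
    return RunResult(archive, best.partition, best.q, history)
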