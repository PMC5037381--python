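"""Decomposition machinery: weights, membranes, migration, archive, full runs."""

import numpy as np
import pytest

import moeadm
from moeadm.graph_io import Partition
from moeadm.moea_dm import (
    AlgorithmConfig,
    Archive,
    ArchiveEntry,
    build_membranes,
    evolve_membrane,
    generate_weights,
    history_to_csv,
    migrate,
    run,
    run_moead_baseline,
    _evaluate_solution,
    _Solution,
)
from moeadm.objectives import dominates, tchebycheff


SMALL = AlgorithmConfig(popsize=24, cell_num=8, niche=3, maxgen=30, seed=5)


class TestWeights:
    def test_three_vectors(self):
        assert generate_weights(3) == [(0.0, 1.0), (0.5, 0.5), (1.0, 0.0)]

    def test_two_vectors(self):
        assert generate_weights(2) == [(0.0, 1.0), (1.0, 0.0)]

    @pytest.mark.parametrize("k", [1, 2, 7, 40])
    def test_simplex_membership(self, k):
        for w in generate_weights(k):
            assert 0 <= w[0] <= 1 and 0 <= w[1] <= 1
            assert w[0] + w[1] == pytest.approx(1.0)


class TestBuildMembranes:
    def test_default_shape(self, karate_net, rng):
        membranes, z = build_membranes(AlgorithmConfig(seed=0), karate_net, rng)
        assert len(membranes) == 40
        assert all(len(m.solutions) == 3 for m in membranes)
        objs = [s.objectives for m in membranes for s in m.solutions]
        assert z == (min(f[0] for f in objs), min(f[1] for f in objs))

    def test_single_membrane_degenerate(self, karate_net, rng):
        cfg = AlgorithmConfig(popsize=12, cell_num=1, niche=1, seed=0)
        membranes, _ = build_membranes(cfg, karate_net, rng)
        assert len(membranes) == 1
        assert len(membranes[0].solutions) == 12

    def test_indivisible_popsize_rejected(self, karate_net, rng):
        with pytest.raises(ValueError, match="divisible"):
            build_membranes(AlgorithmConfig(popsize=10, cell_num=4, niche=2), karate_net, rng)

    def test_seed_determinism(self, karate_net):
        m1, z1 = build_membranes(SMALL, karate_net, np.random.default_rng(3))
        m2, z2 = build_membranes(SMALL, karate_net, np.random.default_rng(3))
        assert z1 == z2
        for a, b in zip(m1, m2):
            for s, t in zip(a.solutions, b.solutions):
                assert np.array_equal(s.genotype, t.genotype)

    def test_niche_contains_self(self, karate_net, rng):
        membranes, _ = build_membranes(SMALL, karate_net, rng)
        for m in membranes:
            assert m.subproblem.index in m.subproblem.neighbor_indices
            assert len(m.subproblem.neighbor_indices) == SMALL.niche


class TestEvolveMembrane:
    def test_membrane_size_conserved_and_z_monotone(self, karate_net, rng):
        membranes, z = build_membranes(SMALL, karate_net, rng)
        for _ in range(20):
            for mem in membranes:
                z_old = z
                _, z = evolve_membrane(mem, membranes, karate_net, SMALL, z, rng)
                assert len(mem.solutions) == 3
                assert z[0] <= z_old[0] and z[1] <= z_old[1]

    def test_better_offspring_replaces_worst(self, bridge, rng):
        net, split = bridge
        cfg = AlgorithmConfig(popsize=4, cell_num=2, niche=2, pm=0.2, seed=1)
        membranes, z = build_membranes(cfg, net, rng)
        mem = membranes[0]
        w = mem.subproblem.weight
        before = max(mem.scalarized(z))
        for _ in range(50):
            _, z = evolve_membrane(mem, membranes, net, cfg, z, rng)
        after = max(mem.scalarized(z))
        assert after <= before  # worst never worsens under a fixed weight


class TestMigrate:
    def _membranes(self, net, cfg, seed):
        return build_membranes(cfg, net, np.random.default_rng(seed))

    def test_identical_solutions_noop(self, bridge):
        net, _ = bridge
        cfg = AlgorithmConfig(popsize=6, cell_num=3, niche=2, seed=0)
        membranes, z = self._membranes(net, cfg, 0)
        clone = membranes[0].solutions[0]
        for mem in membranes:
            mem.solutions = [
                _Solution(clone.genotype.copy(), clone.objectives, clone.partition, clone.q)
                for _ in mem.solutions
            ]
        snapshot = [[s.objectives for s in m.solutions] for m in membranes]
        migrate(membranes, z)
        assert snapshot == [[s.objectives for s in m.solutions] for m in membranes]

    def test_single_membrane_noop(self, bridge):
        net, _ = bridge
        cfg = AlgorithmConfig(popsize=4, cell_num=1, niche=1, seed=0)
        membranes, z = self._membranes(net, cfg, 0)
        migrate(membranes, z)  # must not raise
        assert len(membranes) == 1

    def test_dominating_solution_propagates_along_chain(self, bridge):
        net, split = bridge
        cfg = AlgorithmConfig(popsize=8, cell_num=4, niche=2, seed=0)
        membranes, z = self._membranes(net, cfg, 0)
        # plant the (strictly dominating) natural split in membrane 0
        from moeadm.encoding import encode_partition

        planted = _evaluate_solution(encode_partition(split, net), net)
        z = (
            min(z[0], planted.objectives[0]),
            min(z[1], planted.objectives[1]),
        )
        # make everyone else terrible: all-singleton-ish random genotypes stay;
        # planted replaces membrane 0 entirely
        membranes[0].solutions = [planted] * 2
        migrate(membranes, z)
        in_m1 = any(s.objectives == planted.objectives for s in membranes[1].solutions)
        assert in_m1
        migrate(membranes, z)
        in_m2 = any(s.objectives == planted.objectives for s in membranes[2].solutions)
        assert in_m2


class TestArchive:
    def _entry(self, f):
        part = Partition.from_labels([0])
        return ArchiveEntry(np.zeros(1, dtype=int), f, part, 0.0)

    def test_dominated_candidate_rejected(self):
        a = Archive()
        a.insert(self._entry((0.0, 0.0)))
        assert not a.insert(self._entry((1.0, 1.0)))
        assert len(a) == 1

    def test_dominating_candidate_evicts(self):
        a = Archive()
        a.insert(self._entry((1.0, 2.0)))
        a.insert(self._entry((2.0, 1.0)))
        a.insert(self._entry((0.0, 0.0)))
        assert [e.objectives for e in a.entries] == [(0.0, 0.0)]

    def test_matches_brute_force_filter_on_random_streams(self, rng):
        for _ in range(10):
            stream = [tuple(v) for v in rng.integers(0, 8, size=(60, 2)).astype(float)]
            a = Archive(log_candidates=True)
            parts = [Partition.from_labels([i % 3]) for i in range(3)]
            for i, f in enumerate(stream):
                a.insert(ArchiveEntry(np.zeros(1, dtype=int), f, parts[i % 3], 0.0))
            expected = {
                f for f in stream if not any(dominates(g, f) for g in stream)
            }
            assert {e.objectives for e in a.entries} == expected
            assert a.candidate_log == stream


class TestRun:
    def test_two_disjoint_triangles_hits_exhaustive_max(self):
        net = moeadm.Network.from_edges(
            6, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
        )
        _, qstar = moeadm.exhaustive_best_partition(net, "q")
        assert qstar == pytest.approx(0.5)
        for seed in range(3):
            cfg = AlgorithmConfig(popsize=24, cell_num=8, niche=3, maxgen=50, seed=seed)
            result = run(net, cfg)
            assert result.best_q == pytest.approx(0.5)

    def test_history_and_invariants(self, bridge):
        net, _ = bridge
        cfg = AlgorithmConfig(popsize=12, cell_num=4, niche=2, maxgen=25, seed=2)
        result = run(net, cfg)
        assert len(result.history) == 25
        z1 = [r.z1 for r in result.history]
        z2 = [r.z2 for r in result.history]
        assert z1 == sorted(z1, reverse=True)
        assert z2 == sorted(z2, reverse=True)
        # archive mutually non-dominated
        objs = [e.objectives for e in result.archive.entries]
        for u in objs:
            assert not any(dominates(v, u) for v in objs)

    def test_mode_dispatch_and_baseline_contract(self, bridge):
        net, _ = bridge
        cfg = AlgorithmConfig(popsize=20, niche=5, maxgen=25, seed=3, mode="moea_d")
        result = run(net, cfg)
        assert result.best_q == pytest.approx(5 / 14)
        objs = [e.objectives for e in result.archive.entries]
        for u in objs:
            assert not any(dominates(v, u) for v in objs)

    def test_edgeless_network_rejected(self):
        net = moeadm.Network.from_edges(3, [])
        with pytest.raises(ValueError):
            run(net, SMALL)

    def test_seed_determinism_byte_identical_history(self, karate_net):
        cfg = AlgorithmConfig(popsize=30, cell_num=10, niche=4, maxgen=15, seed=11)
        r1 = run(karate_net, cfg)
        r2 = run(karate_net, cfg)
        assert history_to_csv(r1.history) == history_to_csv(r2.history)
        assert np.array_equal(
            r1.best_partition.assignment, r2.best_partition.assignment
        )

    def test_invalid_config_rejected(self, karate_net):
        with pytest.raises(ValueError):
            run(karate_net, AlgorithmConfig(niche=99))
        with pytest.raises(ValueError):
            run(karate_net, AlgorithmConfig(mode="nope"))


class TestBaseline:
    def test_bridge_reaches_exhaustive_max(self, bridge):
        net, _ = bridge
        for seed in range(3):
            cfg = AlgorithmConfig(popsize=20, niche=5, maxgen=30, seed=seed, mode="moea_d")
            assert run_moead_baseline(net, cfg).best_q == pytest.approx(5 / 14)

    def test_seed_determinism(self, bridge):
        net, _ = bridge
        cfg = AlgorithmConfig(popsize=16, niche=4, maxgen=10, seed=9, mode="moea_d")
        r1 = run_moead_baseline(net, cfg)
        r2 = run_moead_baseline(net, cfg)
        assert history_to_csv(r1.history) == history_to_csv(r2.history)
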