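"""Cluster detection, kinetics bookkeeping and mixing statistics."""

import networkx as nx
import numpy as np
import pytest

from drcluster.clusters import (
    ClusterPartition,
    cluster_kinetics,
    find_clusters,
    kinetics_from_partition,
    mixing_stats,
    partition_trajectory,
)
from drcluster.contacts import ContactParams
from drcluster.system import SystemConfig, Trajectory, plant_clusters
from drcluster.topology import ChainTopology

import oracles


def graph_from_edges(n, edges):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return g


class TestFindClusters:
    def test_edgeless_graph_all_singletons(self):
        comps = find_clusters(graph_from_edges(33, []))
        assert len(comps) == 33
        assert all(len(c) == 1 for c in comps)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_graphs_match_transitive_closure(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        edges = {
            (int(a), int(b))
            for a, b in rng.integers(0, n, size=(n, 2))
            if a != b
        }
        got = find_clusters(graph_from_edges(n, edges))
        expected = oracles.brute_components(n, edges)
        assert got == expected

    def test_sizes_partition_chain_count(self):
        rng = np.random.default_rng(1)
        edges = {(int(a), int(b)) for a, b in rng.integers(0, 20, (15, 2)) if a != b}
        comps = find_clusters(graph_from_edges(20, edges))
        assert sum(len(c) for c in comps) == 20


def static_partition(frames):
    """ClusterPartition from a list of per-frame partitions (sets of ids)."""
    return ClusterPartition(
        frames=[[set(c) for c in f] for f in frames],
        centrals=[{} for _ in frames],
        times=np.arange(len(frames), dtype=float),
    )


class TestKinetics:
    def test_static_clusters_no_events(self):
        p = static_partition([[{0, 1}, {2}]] * 5)
        kin = kinetics_from_partition(p, ["A"] * 3)
        assert kin.join_events == []
        assert kin.leave_events == []
        assert kin.dwell_segments[0] == [(0, 4)]
        assert kin.dwell_segments[2] == []

    def test_join_and_leave_detected(self):
        frames = [
            [{0}, {1}, {2}],
            [{0, 1}, {2}],      # 0 and 1 join
            [{0, 1}, {2}],
            [{0}, {1}, {2}],    # both leave
        ]
        kin = kinetics_from_partition(static_partition(frames), ["A"] * 3)
        assert sorted(kin.join_events) == [(0, 1), (1, 1)]
        assert sorted(kin.leave_events) == [(0, 3), (1, 3)]
        assert kin.dwell_segments[0] == [(1, 2)]

    def test_events_recomputable_from_partition(self):
        rng = np.random.default_rng(4)
        frames = []
        for _ in range(20):
            if rng.random() < 0.5:
                frames.append([{0, 1}, {2}])
            else:
                frames.append([{0}, {1}, {2}])
        p = static_partition(frames)
        k1 = kinetics_from_partition(p, ["A"] * 3)
        k2 = kinetics_from_partition(p, ["A"] * 3)
        assert k1.join_events == k2.join_events
        assert k1.leave_events == k2.leave_events
        # every join is matched by the partition state flipping free->clustered
        for chain, f in k1.join_events:
            assert any(chain in c and len(c) >= 2 for c in frames[f])
            assert any(chain in c and len(c) == 1 for c in frames[f - 1])

    def test_short_trajectory_flagged(self):
        p = static_partition([[{0}, {1}]])
        kin = kinetics_from_partition(p, ["A"] * 2)
        assert kin.status == "too-short"
        assert kin.join_events == []

    def test_planted_cluster_dwell_spans_whole_trajectory(self):
        top = ChainTopology.from_sequence("CH", "DKFG")
        cfg = SystemConfig(box_edge=14.0, species=((top, 5),), seed=0)
        frame = plant_clusters(cfg, [{0, 1, 2}, {3}, {4}], seed=0)
        coords = np.array([frame.coords] * 4)
        traj = Trajectory(frame.system, coords, np.arange(4, dtype=float))
        kin = cluster_kinetics(traj, ContactParams())
        for chain in (0, 1, 2):
            assert kin.dwell_segments[chain] == [(0, 3)]
        assert kin.free_fraction["CH"] == pytest.approx(2 / 5)


class TestMixing:
    def two_species_system(self, na=4, nb=4):
        a = ChainTopology.from_sequence("A", "DKFG")
        b = ChainTopology.from_sequence("B", "DKFG")
        return SystemConfig(box_edge=16.0, species=((a, na), (b, nb)), seed=0)

    def test_label_blind_pairing_gives_enrichment_one(self):
        # equal copies; half the planted pairs heterotypic (A ids 0-3, B 4-7)
        cfg = self.two_species_system()
        frame = plant_clusters(cfg, [{0, 4}, {1, 2}, {5, 6}, {3, 7}], seed=0)
        traj = Trajectory(frame.system, frame.coords[None], np.array([0.0]))
        mix = mixing_stats(traj, ContactParams())
        assert mix.observed_hetero_fraction == pytest.approx(0.5)
        assert mix.expected_hetero_fraction == pytest.approx(0.5)
        assert mix.enrichment == pytest.approx(1.0)

    def test_fully_heterotypic_pairing_enriched(self):
        cfg = self.two_species_system()
        frame = plant_clusters(cfg, [{0, 4}, {1, 5}, {2, 6}, {3, 7}], seed=0)
        traj = Trajectory(frame.system, frame.coords[None], np.array([0.0]))
        mix = mixing_stats(traj, ContactParams())
        assert mix.observed_hetero_fraction == 1.0
        assert mix.enrichment == pytest.approx(2.0)

    def test_homotypic_only_enrichment_below_one(self):
        cfg = self.two_species_system()
        frame = plant_clusters(cfg, [{0, 1}, {2, 3}, {4, 5}, {6, 7}], seed=0)
        traj = Trajectory(frame.system, frame.coords[None], np.array([0.0]))
        mix = mixing_stats(traj, ContactParams())
        assert mix.observed_hetero_fraction == 0.0
        assert mix.enrichment == 0.0

    def test_no_edges_flagged_not_nan(self):
        cfg = self.two_species_system(2, 2)
        frame = plant_clusters(cfg, [{0}, {1}, {2}, {3}], seed=0)
        traj = Trajectory(frame.system, frame.coords[None], np.array([0.0]))
        mix = mixing_stats(traj, ContactParams())
        assert mix.status == "no-inter-chain-edges"
        assert mix.observed_hetero_fraction is None
        assert mix.enrichment is None

    def test_single_species_rejected(self):
        top = ChainTopology.from_sequence("A", "DKFG")
        cfg = SystemConfig(box_edge=10.0, species=((top, 3),), seed=0)
        frame = plant_clusters(cfg, [{0}, {1}, {2}], seed=0)
        traj = Trajectory(frame.system, frame.coords[None], np.array([0.0]))
        with pytest.raises(ValueError):
            mixing_stats(traj, ContactParams())


class TestPartitionInvariants:
    def test_sizes_sum_to_chain_count_per_frame(self, sticky_partition):
        part, n_chains = sticky_partition
        for comps in part.frames:
            assert sum(len(c) for c in comps) == n_chains

    def test_central_chain_member_of_component(self, sticky_partition):
        part, _ = sticky_partition
        for comps, centrals in zip(part.frames, part.centrals):
            for ci, central in centrals.items():
                assert central in comps[ci]


@pytest.fixture(scope="module")
def sticky_partition():
    from drcluster.dynamics import simulate
    from drcluster.system import build_system

    top = ChainTopology.from_sequence("STK6", "DKFDKF")
    cfg = SystemConfig(box_edge=11.0, species=((top, 8),), seed=4).with_chi(4.0)
    traj = simulate(build_system(cfg), n_steps=20000, dt_ns=0.002, save_every=2000, seed=4)
    return partition_trajectory(traj, ContactParams()), 8
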