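"""Contact-map machinery against constructed frames and brute-force oracles."""

import numpy as np
import pytest

from drcluster.contacts import (
    ContactMatrix,
    ContactParams,
    NoContributingFramesError,
    bead_contacts,
    beads_to_residues,
    central_chain_matrix,
    interaction_graph,
    intra_chain_matrix,
    project_1d,
    two_chain_matrix,
)
from drcluster.system import Frame, System, SystemConfig, Trajectory, build_system
from drcluster.dynamics import simulate
from drcluster.topology import ChainTopology

import oracles


def make_system(n_chains=2, seq="GGGG", box=10.0, chi=1.0, bpr=1):
    top = ChainTopology.from_sequence("CH", seq, beads_per_residue=bpr)
    cfg = SystemConfig(box_edge=box, species=((top, n_chains),), seed=0).with_chi(chi)
    return System.from_config(cfg)


def frame_with_coords(system, coords, t=0.0):
    return Frame(system, np.mod(np.asarray(coords, dtype=float), system.config.box_edge), t)


def straight_chain(n, origin, spacing=0.38, axis=0):
    c = np.tile(np.asarray(origin, dtype=float), (n, 1))
    c[:, axis] += np.arange(n) * spacing
    return c


class TestBeadContacts:
    def two_bead_frame(self, d):
        sys_ = make_system(n_chains=2, seq="G")
        return frame_with_coords(sys_, [[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]])

    def test_cutoff_is_strict_less_than(self):
        assert len(bead_contacts(self.two_bead_frame(0.49), ContactParams())) == 1
        assert len(bead_contacts(self.two_bead_frame(0.51), ContactParams())) == 0
        assert len(bead_contacts(self.two_bead_frame(0.5), ContactParams())) == 0

    def test_minimum_image_across_box_faces(self):
        sys_ = make_system(n_chains=2, seq="G")
        frame = frame_with_coords(sys_, [[0.1, 5, 5], [9.9, 5, 5]])  # 0.2 nm apart
        assert len(bead_contacts(frame, ContactParams())) == 1

    def test_intra_exclusion_window(self):
        sys_ = make_system(n_chains=1, seq="G" * 6)
        # fold the chain so bead 0 is near bead 2 (excluded) and bead 5 (kept)
        coords = straight_chain(6, [2, 2, 2], spacing=0.3)
        coords[5] = coords[0] + [0.0, 0.35, 0.0]
        coords[2] = coords[0] + [0.0, 0.0, 0.35]
        frame = frame_with_coords(sys_, coords)
        pairs = {tuple(p) for p in bead_contacts(frame, ContactParams(intra_exclusion=3))}
        assert (0, 5) in pairs
        assert all(abs(i - j) >= 3 for i, j in pairs)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_frames_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        sys_ = make_system(n_chains=4, seq="DKFGDK", box=6.0, bpr=1 + seed % 2)
        frame = frame_with_coords(sys_, rng.uniform(0, 6.0, (sys_.n_beads, 3)))
        params = ContactParams(cutoff=0.6, intra_exclusion=2 + seed % 3)
        got = {tuple(p) for p in bead_contacts(frame, params)}
        assert got == oracles.brute_bead_contacts(frame, params)

    def test_larger_cutoff_never_removes_contacts(self):
        sys_ = make_system(n_chains=3, seq="DKFG")
        rng = np.random.default_rng(5)
        frame = frame_with_coords(sys_, rng.uniform(0, 10, (12, 3)))
        small = {tuple(p) for p in bead_contacts(frame, ContactParams(cutoff=0.5))}
        large = {tuple(p) for p in bead_contacts(frame, ContactParams(cutoff=0.8))}
        assert small <= large


class TestInteractionGraph:
    def test_isolated_chains_edgeless(self):
        sys_ = make_system(n_chains=3, seq="GG", box=12.0)
        coords = np.concatenate(
            [straight_chain(2, [1 + 4 * i, 1, 1]) for i in range(3)]
        )
        g = interaction_graph(frame_with_coords(sys_, coords), ContactParams())
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3

    def test_threshold_above_contact_count_drops_edge(self):
        sys_ = make_system(n_chains=2, seq="GGG")
        # stack three bead pairs 0.4 nm apart -> exactly 3 inter-chain contacts
        a = straight_chain(3, [2, 2, 2], spacing=1.2)
        b = a + [0.0, 0.4, 0.0]
        frame = frame_with_coords(sys_, np.concatenate([a, b]))
        assert interaction_graph(frame, ContactParams(chain_threshold=3)).number_of_edges() == 1
        assert interaction_graph(frame, ContactParams(chain_threshold=4)).number_of_edges() == 0


class TestCentralChainMatrix:
    def test_single_contact_single_neighbor(self):
        sys_ = make_system(n_chains=2, seq="GGG", box=12.0)
        a = straight_chain(3, [2, 2, 2], spacing=1.2)
        b = straight_chain(3, [2, 2, 2], spacing=1.2)
        b += [4.0, 0.0, 0.0]
        b[0] = a[2] + [0.45, 0.0, 0.0]  # single bead pair (2, 0) in contact
        traj = Trajectory(sys_, np.array([np.concatenate([a, b])]), np.array([0.0]))
        m = central_chain_matrix(traj, ContactParams())
        expected = np.zeros((3, 3))
        expected[2, 0] = 1.0
        np.testing.assert_array_equal(m.values, expected)
        assert m.frames_contributing == 1

    def test_two_neighbors_same_contact_average_is_one(self):
        sys_ = make_system(n_chains=3, seq="G", box=12.0)
        # chains 1 and 2 both touch chain 0; chain 0 has degree 2 -> central
        coords = np.array([[5, 5, 5], [5.45, 5, 5], [4.55, 5, 5]], dtype=float)
        traj = Trajectory(sys_, coords[None], np.array([0.0]))
        m = central_chain_matrix(traj, ContactParams())
        np.testing.assert_array_equal(m.values, [[1.0]])

    def test_no_cluster_frames_raises(self):
        sys_ = make_system(n_chains=2, seq="GG", box=12.0)
        a = straight_chain(2, [1, 1, 1])
        b = straight_chain(2, [6, 6, 6])
        traj = Trajectory(sys_, np.concatenate([a, b])[None], np.array([0.0]))
        with pytest.raises(NoContributingFramesError):
            central_chain_matrix(traj, ContactParams())

    def test_score_bounds(self, sticky_trajectory):
        m = central_chain_matrix(sticky_trajectory, ContactParams())
        assert np.all(m.values >= 0)
        assert np.all(m.values <= 1)


class TestTwoChainMatrix:
    def test_never_in_contact_gives_zero_matrix_all_frames_counted(self):
        sys_ = make_system(n_chains=2, seq="GG", box=12.0)
        a = straight_chain(2, [1, 1, 1])
        b = straight_chain(2, [6, 6, 6])
        coords = np.concatenate([a, b])
        traj = Trajectory(sys_, np.array([coords, coords]), np.array([0.0, 1.0]))
        m = two_chain_matrix(traj, ContactParams())
        assert np.all(m.values == 0)
        assert m.frames_contributing == 2

    def test_permanent_contact_scores_one(self):
        sys_ = make_system(n_chains=2, seq="GG", box=12.0)
        a = straight_chain(2, [2, 2, 2])
        b = a + [0.0, 0.45, 0.0]
        coords = np.concatenate([a, b])
        traj = Trajectory(sys_, np.array([coords, coords]), np.array([0.0, 1.0]))
        m = two_chain_matrix(traj, ContactParams())
        assert m.values[0, 0] == 1.0
        assert m.values[1, 1] == 1.0

    def test_requires_exactly_two_chains(self):
        sys_ = make_system(n_chains=3, seq="GG", box=12.0)
        coords = np.zeros((6, 3))
        traj = Trajectory(sys_, coords[None], np.array([0.0]))
        with pytest.raises(ValueError):
            two_chain_matrix(traj, ContactParams())


class TestIntraChainMatrix:
    def test_extended_chain_zero(self):
        sys_ = make_system(n_chains=1, seq="G" * 8, box=12.0)
        traj = Trajectory(
            sys_, straight_chain(8, [1, 1, 1])[None], np.array([0.0])
        )
        m = intra_chain_matrix(traj, ContactParams())
        assert np.all(m.values == 0)

    def test_hairpin_contact_detected(self):
        sys_ = make_system(n_chains=1, seq="G" * 12, box=14.0)
        coords = straight_chain(12, [2, 2, 2], spacing=0.38)
        coords[10] = coords[0] + [0.0, 0.4, 0.0]  # bead 0 touches bead 10
        m = intra_chain_matrix(
            Trajectory(sys_, coords[None], np.array([0.0])), ContactParams()
        )
        assert m.values[0, 10] == 1.0
        assert m.values[10, 0] == 1.0

    def test_exclusion_band_is_zero(self, sticky_trajectory):
        m = intra_chain_matrix(sticky_trajectory, ContactParams(intra_exclusion=3))
        n = m.values.shape[0]
        for i in range(n):
            for j in range(max(0, i - 2), min(n, i + 3)):
                assert m.values[i, j] == 0


class TestBeadsToResidues:
    def test_identity_for_one_bead_per_residue(self):
        top = ChainTopology.from_sequence("CH", "GGG")
        values = np.arange(9.0).reshape(3, 3)
        m = ContactMatrix(values, "bead", "pair", 1, 1, 0.5, "CH")
        np.testing.assert_array_equal(beads_to_residues(m, top).values, values)

    def test_max_rule_two_beads_per_residue(self):
        top = ChainTopology.from_sequence("CH", "GG", beads_per_residue=2)
        rng = np.random.default_rng(0)
        values = rng.uniform(size=(4, 4))
        m = ContactMatrix(values, "bead", "pair", 1, 1, 0.5, "CH")
        got = beads_to_residues(m, top).values
        expected = oracles.brute_beads_to_residues(values, top.bead_residue)
        np.testing.assert_allclose(got, expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_matrices_match_oracle(self, seed):
        top = ChainTopology.from_sequence("CH", "GGGG", beads_per_residue=2)
        rng = np.random.default_rng(seed)
        values = rng.uniform(size=(8, 8))
        m = ContactMatrix(values, "bead", "pair", 1, 1, 0.5, "CH")
        np.testing.assert_allclose(
            beads_to_residues(m, top).values,
            oracles.brute_beads_to_residues(values, top.bead_residue),
        )

    def test_dimension_mismatch_rejected(self):
        top = ChainTopology.from_sequence("CH", "GGG")
        m = ContactMatrix(np.zeros((4, 4)), "bead", "pair", 1, 1, 0.5, "CH")
        with pytest.raises(ValueError):
            beads_to_residues(m, top)


class TestProject1D:
    def residue_matrix(self, values):
        return ContactMatrix(values, "residue", "pair", 1, 1, 0.5, "CH")

    def test_zero_matrix(self):
        assert np.all(project_1d(self.residue_matrix(np.zeros((4, 4)))) == 0)

    def test_symmetric_entry_contributes_to_both_residues(self):
        v = np.zeros((4, 4))
        v[1, 3] = v[3, 1] = 1.0
        scores = project_1d(self.residue_matrix(v))
        assert scores[1] == 1.0
        assert scores[3] == 1.0

    def test_matches_oracle_on_random_matrix(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(size=(6, 6))
        np.testing.assert_allclose(
            project_1d(self.residue_matrix(v)), oracles.brute_project_1d(v)
        )


@pytest.fixture(scope="module")
def sticky_trajectory():
    top = ChainTopology.from_sequence("STK6", "DKFDKF")
    cfg = SystemConfig(box_edge=11.0, species=((top, 8),), seed=2).with_chi(4.0)
    frame = build_system(cfg)
    return simulate(frame, n_steps=30000, dt_ns=0.002, save_every=1500, seed=2)


class TestInvariants:
    def test_translation_and_periodic_invariance(self, sticky_trajectory):
        params = ContactParams()
        base = central_chain_matrix(sticky_trajectory, params).values
        box = sticky_trajectory.system.config.box_edge
        shifted = Trajectory(
            sticky_trajectory.system,
            np.mod(sticky_trajectory.coords + np.array([3.3, box, -7.1]), box),
            sticky_trajectory.times,
        )
        np.testing.assert_allclose(
            central_chain_matrix(shifted, params).values, base
        )

    def test_chain_relabelling_invariance_unambiguous_cluster(self):
        # a star: one hub touching three spokes at distinct bead pairs; the
        # central chain is unambiguous, so any relabelling yields the same
        # matrix (ties are otherwise broken by chain id, which relabelling
        # would move)
        sys_ = make_system(n_chains=4, seq="GGGG", box=14.0)
        hub = straight_chain(4, [5, 5, 5], spacing=1.2)
        spokes = []
        for k in range(3):
            s = straight_chain(4, [1, 1, 1 + 4 * k])
            s[0] = hub[k] + [0.0, 0.45, 0.0]
            s[1:] = s[0] + np.outer(np.arange(1, 4), [0.0, 1.2, 0.0])
            spokes.append(s)
        coords = np.concatenate([hub] + spokes)
        params = ContactParams()
        base = central_chain_matrix(
            Trajectory(sys_, coords[None], np.array([0.0])), params
        ).values
        rng = np.random.default_rng(1)
        for _ in range(3):
            perm = rng.permutation(4)
            order = np.concatenate([np.arange(4) + 4 * c for c in perm])
            relabelled = Trajectory(sys_, coords[None][:, order, :], np.array([0.0]))
            np.testing.assert_allclose(
                central_chain_matrix(relabelled, params).values, base
            )
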