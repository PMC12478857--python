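"""Hydrogen-bond detection, per-anion statistics, bridging censuses."""

import numpy as np
import pytest

import cycshell as cs
from cycshell.core import Frame, System
from cycshell.residues import label_atoms

from _oracles import brute_force_hbonds

D_CUT, ANGLE_CUT = 3.0, 150.0


def _random_donor_acceptor_system(n_donors, n_acceptors, box, seed):
    """Dense random donors (D-H groups) and acceptors in a periodic box."""
    rng = np.random.default_rng(seed)
    raw, coords = [], []
    for i in range(n_donors):
        d = rng.uniform(0, box[0], 3)
        w = rng.normal(size=3)
        w /= np.linalg.norm(w)
        raw.append({"name": "D", "residue_name": "DON",
                    "residue_index": i, "peptide_id": i})
        raw.append({"name": "HD", "residue_name": "DON",
                    "residue_index": i, "peptide_id": i})
        coords.extend([d, d + w])
    for j in range(n_acceptors):
        raw.append({"name": "A", "residue_name": "ACC",
                    "residue_index": n_donors + j, "peptide_id": -1})
        coords.append(rng.uniform(0, box[0], 3))
    return System(label_atoms(raw), Frame(np.array(coords), box))


class TestFindHbonds:
    def test_recovers_exactly_the_planted_triples(self):
        system, truth = cs.plant_hbond_set(5, 3, 2, box=(150, 150, 150),
                                           seed=3)
        got = {(r.donor_heavy, r.hydrogen, r.acceptor_heavy)
               for r in cs.find_hbonds(system)}
        assert got == set(truth.hbond_triples)

    def test_relaxed_distance_admits_far_decoys_only(self):
        system, truth = cs.plant_hbond_set(5, 3, 2, box=(150, 150, 150),
                                           seed=3)
        records = cs.find_hbonds(system, d_cut=4.0)
        assert len(records) == 8  # bent decoys still excluded

    def test_matches_all_pairs_oracle_on_dense_random_input(self):
        box = np.array([30.0, 30.0, 30.0])
        system = _random_donor_acceptor_system(250, 250, box, seed=13)
        got = {(r.donor_heavy, r.hydrogen, r.acceptor_heavy)
               for r in cs.find_hbonds(system)}
        assert got == brute_force_hbonds(system)
        assert len(got) > 0  # dense enough to be a meaningful check

    def test_monotone_in_both_thresholds(self):
        box = np.array([30.0, 30.0, 30.0])
        system = _random_donor_acceptor_system(150, 150, box, seed=14)
        base = {(r.donor_heavy, r.hydrogen, r.acceptor_heavy)
                for r in cs.find_hbonds(system)}
        relaxed = {(r.donor_heavy, r.hydrogen, r.acceptor_heavy)
                   for r in cs.find_hbonds(system, d_cut=3.5,
                                           angle_cut=140.0)}
        assert base <= relaxed

    def test_output_sorted_by_donor_acceptor(self):
        system, _ = cs.plant_hbond_set(10, 0, 0, box=(200, 200, 200), seed=4)
        records = cs.find_hbonds(system)
        keys = [(r.donor_heavy, r.acceptor_heavy) for r in records]
        assert keys == sorted(keys)

    def test_rotation_and_translation_invariance(self):
        from scipy.spatial.transform import Rotation
        system, truth = cs.plant_hbond_set(6, 4, 4, box=(150, 150, 150),
                                           seed=5)
        rot = Rotation.from_rotvec([0.3, -0.8, 0.5])
        center = system.box / 2
        moved = System(system.topology, Frame(
            rot.apply(system.coords - center) + center + 2.0, system.box))
        got = {(r.donor_heavy, r.hydrogen, r.acceptor_heavy)
               for r in cs.find_hbonds(moved)}
        assert got == set(truth.hbond_triples)

    def test_jittered_frames_match_oracle_with_calibrated_band(self):
        """Under 0.1 Å thermal jitter the detector equals the all-pairs
        oracle frame by frame; planted-bond survival follows the
        oracle-calibrated band (margins are smaller than the jitter)."""
        system, _ = cs.plant_hbond_set(20, 10, 10, box=(160, 160, 160),
                                       seed=11)
        traj = cs.make_jitter_trajectory(system, 60, 0.1, seed=12)
        counts = []
        for i in range(len(traj)):
            got = {(r.donor_heavy, r.hydrogen, r.acceptor_heavy)
                   for r in cs.find_hbonds(traj[i])}
            assert got == brute_force_hbonds(traj[i])
            counts.append(len(got))
        counts = np.array(counts)
        assert counts[0] == 20            # frame 0 is the unjittered input
        assert counts.min() >= 13 and counts.max() <= 20
        assert 16.0 <= counts.mean() <= 17.2


class TestHbondsPerAnion:
    def test_uniform_two_bond_anions(self):
        system, _ = cs.plant_bridges(10, 2, 0, 0, box=(300, 300, 300),
                                     seed=6)
        stats = cs.hbonds_per_anion(system)
        assert stats.mean == pytest.approx(2.0)
        assert stats.pmf == {2: 1.0}
        assert stats.fraction_by_residue == {"ARG": 1.0}
        assert stats.mean_rounded == 2

    def test_no_bonds_is_a_delta_at_zero(self):
        system, _ = cs.plant_bridges(0, 2, 0, 5, box=(150, 150, 150), seed=7)
        stats = cs.hbonds_per_anion(system)
        assert stats.mean == 0.0
        assert stats.pmf == {0: 1.0}
        assert stats.mean_rounded == 0

    def test_mixed_fixture_pmf_is_the_planted_multiset(self):
        system, _ = cs.plant_bridges(3, 4, 5, 2, box=(300, 300, 300), seed=8)
        stats = cs.hbonds_per_anion(system)
        # 3 anions with 4 bonds, 5 with 1, 2 with 0
        assert stats.pmf == {4: 0.3, 1: 0.5, 0: 0.2}
        assert stats.mean == pytest.approx(1.7)


class TestBridging:
    def test_planted_ratios(self):
        system, truth = cs.plant_bridges(4, 2, 6, 10, box=(250, 250, 250),
                                         seed=5)
        rep = cs.find_bridging_ions(system)
        assert rep.n_bridging == 4
        assert rep.n_condensed == 10
        assert rep.n_total == 20
        assert rep.ratio_total == pytest.approx(0.20)
        assert rep.ratio_condensed == pytest.approx(0.40)
        assert rep.bridging_ids == truth.bridging_ion_ids
        assert rep.condensed_ids == truth.condensed_ion_ids

    def test_one_anion_bridging_six_peptides(self):
        """The multidentate motif: a single anion hydrogen-bonded to six
        peptides; every condensed ion bridges."""
        system, _ = cs.plant_bridges(6, 6, 0, 0, box=(300, 300, 300), seed=9)
        rep = cs.find_bridging_ions(system)
        assert rep.n_bridging == 6
        assert rep.ratio_condensed == pytest.approx(1.0)
        assert all(len(p) == 6 for p in rep.peptides_by_anion.values())

    def test_all_free_gives_zero_and_null(self):
        system, _ = cs.plant_bridges(0, 2, 0, 5, box=(150, 150, 150), seed=7)
        rep = cs.find_bridging_ions(system)
        assert rep.ratio_total == 0.0
        assert rep.ratio_condensed is None

    def test_ordering_invariant(self):
        for seed in (1, 2, 3):
            system, _ = cs.plant_bridges(2, 3, 3, 4, box=(250, 250, 250),
                                         seed=seed)
            rep = cs.find_bridging_ions(system)
            assert rep.n_bridging <= rep.n_condensed <= rep.n_total


class TestBackboneCensus:
    def _oracle(self, system, cutoff=3.85):
        topo = system.topology
        o_ids = [a.atom_id for a in topo
                 if "backbone" in a.roles and "acceptor_heavy" in a.roles]
        h_ids = [a.atom_id for a in topo
                 if "backbone" in a.roles and "hydrogen" in a.roles]
        per_o = {}
        for o in o_ids:
            n = 0
            for h in h_ids:
                if topo[h].residue_index == topo[o].residue_index:
                    continue
                if cs.minimum_image_distance(system.coords[o],
                                             system.coords[h],
                                             system.box) <= cutoff:
                    n += 1
            per_o[o] = n
        return float(np.mean(list(per_o.values()))), per_o

    def test_stacked_rings_match_oracle(self):
        system = cs.build_shell(cs.ShellSpec(n_units=1, peptides_per_unit=2))
        mean, per_o = cs.backbone_hb_census(system)
        exp_mean, exp_per_o = self._oracle(system)
        assert per_o == exp_per_o
        assert mean == pytest.approx(exp_mean)
        assert mean > 0  # stacking register puts amide H near carbonyl O

    def test_single_ring_has_no_interpeptide_contribution(self):
        system = cs.build_shell(cs.ShellSpec(n_units=1, peptides_per_unit=1))
        mean_single, per_o = cs.backbone_hb_census(system)
        assert (mean_single, per_o) == \
            pytest.approx(self._oracle(system))
        # every contributing hydrogen is on the same (only) peptide
        topo = system.topology
        assert set(topo.peptide_id) == {0}

    def test_random_gas_matches_oracle(self, water_pdb):
        gas, _ = cs.plant_hbond_set(0, 6, 6, box=(120, 120, 120), seed=10)
        shell = cs.build_shell(cs.ShellSpec(n_units=2, seed=3))
        mean, per_o = cs.backbone_hb_census(shell)
        assert (mean, per_o) == pytest.approx(self._oracle(shell))
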