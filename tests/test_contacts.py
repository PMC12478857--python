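"""Condensation series, contact censuses, RDF/hydration statistics."""

import numpy as np
import pytest

import cycshell as cs
from cycshell.contacts import RDFResult
from cycshell.core import Frame, System
from cycshell.residues import label_atoms

from _oracles import brute_force_contacts, brute_force_pair_counts


def _single_site_peptides(positions, box, resname="DLE", name="CG"):
    """Each position becomes its own single-residue mini peptide."""
    raw = [{"name": name, "residue_name": resname, "residue_index": i,
            "peptide_id": i} for i in range(len(positions))]
    return System(label_atoms(raw), Frame(np.asarray(positions, float),
                                          np.asarray(box, float)))


class TestCondensation:
    def test_planted_condensed_count(self):
        system, truth = cs.plant_bridges(0, 2, 10, 5, box=(250, 250, 250),
                                         seed=5)
        ser = cs.condensation_timeseries(system)
        assert list(ser.counts) == [10]
        assert len(truth.condensed_ion_ids) == 10

    def test_zero_jitter_series_is_constant(self):
        system, _ = cs.plant_bridges(2, 2, 3, 4, box=(250, 250, 250), seed=6)
        traj = cs.make_jitter_trajectory(system, 5, 0.0, seed=1)
        ser = cs.condensation_timeseries(traj)
        assert np.all(ser.counts == ser.counts[0])

    def test_per_frame_counts_match_all_pairs_oracle(self):
        system, _ = cs.plant_bridges(2, 2, 4, 6, box=(250, 250, 250), seed=7)
        traj = cs.make_jitter_trajectory(system, 4, 0.3, seed=2)
        ser = cs.condensation_timeseries(traj)
        topo = traj.topology
        ion_heavy = [a.atom_id for a in topo
                     if a.species == "anion" and a.element != "H"]
        pep_heavy = [a.atom_id for a in topo
                     if a.species == "peptide" and a.element != "H"]
        for k in range(len(traj)):
            pairs = brute_force_contacts(traj[k], ion_heavy, pep_heavy, 3.0)
            condensed = {topo.residue_index[i] for i, _ in pairs}
            assert ser.counts[k] == len(condensed)

    def test_per_arg_normalization(self):
        # 10 mono-bonded anions on 10 single-Arg peptides: 1 ion per Arg
        system, _ = cs.plant_bridges(0, 2, 10, 0, box=(250, 250, 250),
                                     seed=5)
        ser = cs.condensation_timeseries(system)
        assert ser.per_arg_mean == pytest.approx(1.0)


class TestSidechainCensus:
    def test_planted_census_matches_truth_exactly(self):
        system, truth = cs.plant_bridges(3, 2, 2, 1, box=(250, 250, 250),
                                         seed=8)
        cen = cs.sidechain_contact_census(system)
        # every bridging anion touches 2 Arg peptides, each mono one
        assert cen.counts["ARG"] == 3 * 2 + 2
        assert all(s == {"ARG"} for s in cen.residues_by_ion.values())

    def test_no_ion_contacts_gives_zero(self):
        # far decoys: donor-acceptor 3.1-4.0 Å, beyond the 3.0 Å contact rule
        system, _ = cs.plant_hbond_set(0, 6, 0, box=(150, 150, 150), seed=9)
        cen = cs.sidechain_contact_census(system)
        assert all(v == 0 for v in cen.counts.values())

    def test_permutation_invariance_of_counts(self):
        system, _ = cs.plant_bridges(2, 3, 2, 2, box=(250, 250, 250),
                                     seed=10)
        cen1 = cs.sidechain_contact_census(system)
        # reverse atom order, rebuild ids accordingly
        topo = system.topology
        order = np.arange(len(topo))[::-1]
        raw = [{"name": topo[i].name, "residue_name": topo[i].residue_name,
                "residue_index": topo[i].residue_index,
                "peptide_id": topo[i].peptide_id} for i in order]
        system2 = System(label_atoms(raw),
                         Frame(system.coords[order], system.box))
        cen2 = cs.sidechain_contact_census(system2)
        assert cen1.counts == cen2.counts

    def test_ions_on_420_of_432_shell_dleu_sites(self, default_shell):
        """Anions planted against the d-Leu sites of 420 of the 432 shell
        peptides are counted exactly; Arg/Gln stay untouched."""
        topo = default_shell.topology
        coords = default_shell.coords
        n_pep = topo.peptide_id.max() + 1
        cg_of, ca_of = {}, {p: [] for p in range(n_pep)}
        for a in topo:
            if a.residue_name == "DLE" and a.name == "CG" \
                    and a.peptide_id not in cg_of:
                cg_of[a.peptide_id] = a.atom_id
            if a.name == "CA":
                ca_of[a.peptide_id].append(a.atom_id)
        raw = [{"name": a.name, "residue_name": a.residue_name,
                "residue_index": a.residue_index,
                "peptide_id": a.peptide_id} for a in topo]
        res_base = max(a.residue_index for a in topo) + 1
        ions = []
        for i, p in enumerate(range(420)):
            center = coords[ca_of[p]].mean(axis=0)
            v = coords[cg_of[p]] - center
            # 2.5 Å from the d-Leu site, toward the (empty) ring interior
            ions.append(center + v * (1 - 2.5 / np.linalg.norm(v)))
            raw.append({"name": "F", "residue_name": "F",
                        "residue_index": res_base + i, "peptide_id": -1})
        system = System(label_atoms(raw),
                        Frame(np.vstack([coords, ions]), default_shell.box))
        cen = cs.sidechain_contact_census(system)
        assert cen.counts["DLE"] == 420
        assert cen.counts["ARG"] == 0
        assert cen.counts["GLN"] == 0


class TestInterpeptideContacts:
    def test_single_pair_at_contact_distance(self):
        system = _single_site_peptides([[10, 10, 10], [12.8, 10, 10]],
                                       (50, 50, 50))
        per_chain, mean = cs.interpeptide_residue_contacts(system, "DLE")
        assert per_chain == {0: 1, 1: 1}
        assert mean == 1.0

    def test_isolated_peptide_has_no_contacts(self):
        system = _single_site_peptides([[10, 10, 10]], (50, 50, 50))
        per_chain, mean = cs.interpeptide_residue_contacts(system, "DLE")
        assert per_chain == {0: 0} and mean == 0.0

    def test_dense_random_fixture_matches_oracle(self):
        rng = np.random.default_rng(15)
        pos = rng.uniform(0, 30, (60, 3))
        system = _single_site_peptides(pos, (30, 30, 30))
        per_chain, mean = cs.interpeptide_residue_contacts(system, "DLE")
        ids = list(range(60))
        pairs = brute_force_contacts(system, ids, ids, 3.0)
        expect = {i: len({j for a, j in pairs if a == i}) for i in ids}
        assert per_chain == expect


class TestPairRDF:
    def test_ideal_gas_is_uniform(self):
        traj, _ = cs.make_gas_fixture(2000, (60, 60, 60), seed=16)
        rdf = cs.pair_rdf(traj, "species=peptide", "species=peptide",
                          bin_width=0.5, r_max=25.0)
        sel = rdf.bin_mid > 3.0
        expected_pairs = (rdf.bulk_density
                          * np.diff(4 / 3 * np.pi * rdf.bin_edges ** 3))
        se = 1.0 / np.sqrt(expected_pairs * rdf.n_centers)
        assert np.all(np.abs(rdf.g[sel] - 1.0) < 4.0 * se[sel])

    def test_hydration_fixture_peak_and_gap(self):
        system, _ = cs.plant_hydration(7, 3.1, 50, box=(60, 60, 60), seed=2)
        rdf = cs.pair_rdf(system, "species=anion",
                          "species=water and element=O",
                          bin_width=0.1, r_max=10.0)
        peak_r = rdf.bin_mid[np.argmax(rdf.g)]
        assert 3.0 <= peak_r <= 3.2
        fm = cs.first_minimum(rdf)
        assert 3.2 < fm < 5.0

    def test_raw_pair_counts_match_all_pairs_oracle(self):
        traj, _ = cs.make_gas_fixture(300, (25, 25, 25), seed=17)
        system = traj[0]
        c_ids = np.arange(0, 300, 3)
        t_ids = np.arange(300)
        rdf = cs.pair_rdf(traj, c_ids, t_ids, bin_width=0.25, r_max=10.0)
        expect = brute_force_pair_counts(system, c_ids, t_ids, rdf.bin_edges)
        assert np.allclose(rdf.pair_counts * len(c_ids), expect)

    def test_r_max_must_fit_half_box(self):
        traj, _ = cs.make_gas_fixture(10, (20, 20, 20), seed=18)
        with pytest.raises(cs.DomainError):
            cs.pair_rdf(traj, None, None, r_max=15.0)


class TestFirstMinimum:
    def _curve(self, minimum=3.35):
        r = np.arange(0.025, 8.0, 0.05)
        g = (1.0 + 2.5 * np.exp(-((r - 2.8) / 0.25) ** 2)
             - 0.9 * np.exp(-((r - minimum) / 0.25) ** 2))
        return RDFResult(bin_edges=np.arange(0.0, 8.0 + 0.025, 0.05), g=g,
                         pair_counts=g, bulk_density=1.0, n_centers=1)

    def test_analytic_minimum_recovered(self):
        fm = cs.first_minimum(self._curve(3.35))
        assert fm == pytest.approx(3.35, abs=0.05)

    def test_monotone_curve_raises(self):
        r = np.arange(0.05, 5.0, 0.1)
        rdf = RDFResult(bin_edges=np.arange(0.0, 5.05, 0.1), g=r.copy(),
                        pair_counts=r, bulk_density=1.0, n_centers=1)
        with pytest.raises(cs.AnalysisError):
            cs.first_minimum(rdf)

    def test_hydration_minimum_separates_shells(self):
        system, truth = cs.plant_hydration(16, 4.2, 100, box=(40, 40, 40),
                                           seed=19)
        rdf = cs.pair_rdf(system, "species=anion",
                          "species=water and element=O",
                          bin_width=0.1, r_max=9.0)
        fm = cs.first_minimum(rdf)
        assert 4.3 < fm < 6.0
        count = cs.coordination_number(system, "species=anion",
                                       "species=water and element=O", fm)
        assert count == truth.coordination_by_center[0] == 16


class TestCoordination:
    def test_planted_coordination(self):
        system, _ = cs.plant_hydration(7, 3.1, 50, box=(60, 60, 60), seed=2)
        assert cs.coordination_number(system, "species=anion",
                                      "species=water and element=O",
                                      3.35) == 7.0

    def test_radius_below_shell_sees_nothing(self):
        system, _ = cs.plant_hydration(7, 3.1, 50, box=(60, 60, 60), seed=2)
        assert cs.coordination_number(system, "species=anion",
                                      "species=water and element=O",
                                      2.0) == 0.0

    def test_nondecreasing_in_radius(self):
        system, _ = cs.plant_hydration(9, 3.0, 40, box=(50, 50, 50), seed=20)
        radii = np.linspace(1.0, 10.0, 25)
        values = [cs.coordination_number(system, "species=anion",
                                         "species=water and element=O", r)
                  for r in radii]
        assert np.all(np.diff(values) >= 0)


class TestWatersPerPeptide:
    def _peptide_with_waters(self, n_shell, n_far, box=(60, 60, 60), seed=21):
        rng = np.random.default_rng(seed)
        raw = [{"name": "PS", "residue_name": "SHP", "residue_index": 0,
                "peptide_id": 0}]
        center = np.asarray(box, float) / 2
        coords = [center]
        res = 1
        for k in range(n_shell + n_far):
            d = 3.0 if k < n_shell else 8.0 + 2 * rng.uniform()
            w = rng.normal(size=3)
            o = center + d * w / np.linalg.norm(w)
            for name, pos in (("O", o), ("H1", o + [0.96, 0, 0]),
                              ("H2", o + [-0.24, 0.93, 0])):
                raw.append({"name": name, "residue_name": "HOH",
                            "residue_index": res, "peptide_id": -1})
                coords.append(pos)
            res += 1
        return System(label_atoms(raw),
                      Frame(np.array(coords), np.asarray(box, float)))

    def test_exactly_ten_first_shell_waters(self):
        system = self._peptide_with_waters(10, 30)
        assert cs.waters_per_peptide(system) == 10.0

    def test_no_nearby_waters(self):
        system = self._peptide_with_waters(0, 20)
        assert cs.waters_per_peptide(system) == 0.0

    def test_no_water_is_a_selection_error(self, small_shell):
        with pytest.raises(cs.SelectionError):
            cs.waters_per_peptide(small_shell)
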