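import numpy as np
import pytest

from nucsox.errors import ArgumentError
from nucsox import contacts as ct
from nucsox import synthetic_data as sd
from nucsox.model_io import Atom, Structure, Trajectory

from _oracles import brute_force_contacts, rigid_transform_structure


def probe_complex(duplex, duplex_map, plan_distances=(2.9, 4.0, 3.4)):
    dyad = duplex_map.forward_key_at(0)
    plan = [
        sd.ContactPlanItem("hbond", dyad[0], dyad[1], "base",
                           plan_distances[0], ("ASN", 54)),
        sd.ContactPlanItem("hydrophobic", *duplex_map.forward_key_at(2)[:2],
                           "backbone", plan_distances[1], ("MET", 57)),
        sd.ContactPlanItem("ionic", *duplex_map.forward_key_at(4)[:2],
                           "backbone", plan_distances[2], ("ARG", 51)),
    ]
    return sd.place_probe(duplex, plan)


def random_toy_complex(rng, n_protein=6):
    """Random DNA fragment with protein residues scattered around it."""
    from nucsox.sequence_design import NucleotideSequence
    bases = "".join(rng.choice(list("ACGT"), size=10))
    dup = sd.build_bdna(NucleotideSequence(bases))
    atoms = list(dup.atoms)
    names = [("ARG", ("NH1", "N")), ("ASN", ("ND2", "N")), ("MET", ("CE", "C")),
             ("PHE", ("CZ", "C")), ("LYS", ("NZ", "N")), ("TYR", ("OH", "O"))]
    anchor_idx = rng.integers(0, len(dup.atoms), size=n_protein)
    for r, (resname, (aname, elem)) in enumerate(names[:n_protein]):
        anchor = dup.atoms[int(anchor_idx[r])].position
        pos = anchor + rng.normal(scale=2.5, size=3)
        atoms.append(Atom(aname, resname, 50 + r, "P", elem, pos))
    return Structure(atoms)


class TestDetectContacts:
    def test_designed_hbond_is_base_specific(self, toy_duplex, toy_duplex_map):
        cx = probe_complex(toy_duplex, toy_duplex_map)
        events = ct.detect_contacts(cx, ct.protein_atoms(cx), ct.dna_atoms(cx))
        hb = [e for e in events if e.contact_class == "hbond"
              and e.protein_residue[1] == 54]
        assert len(hb) == 1 and hb[0].base_specific

    def test_designed_hydrophobic_and_ionic_detected(self, toy_duplex, toy_duplex_map):
        cx = probe_complex(toy_duplex, toy_duplex_map)
        events = ct.detect_contacts(cx, ct.protein_atoms(cx), ct.dna_atoms(cx))
        classes = {(e.protein_residue[1], e.contact_class) for e in events}
        assert (57, "hydrophobic") in classes
        assert (51, "ionic") in classes

    def test_contact_beyond_threshold_ignored(self, toy_duplex, toy_duplex_map):
        cx = probe_complex(toy_duplex, toy_duplex_map, plan_distances=(2.9, 4.6, 3.5))
        events = ct.detect_contacts(cx, ct.protein_atoms(cx), ct.dna_atoms(cx))
        assert not [e for e in events if e.contact_class == "hydrophobic"]

    def test_matches_all_pairs_oracle_on_random_complexes(self):
        rng = np.random.default_rng(12)
        criteria = ct.ContactCriteria()
        for _ in range(40):
            cx = random_toy_complex(rng)
            prot, dna = ct.protein_atoms(cx), ct.dna_atoms(cx)
            got = {(e.protein_residue, e.dna_residue, e.contact_class,
                    e.base_specific)
                   for e in ct.detect_contacts(cx, prot, dna, criteria)}
            assert got == brute_force_contacts(cx, prot, dna, criteria)

    def test_rigid_transform_preserves_event_set(self, toy_duplex, toy_duplex_map):
        cx = probe_complex(toy_duplex, toy_duplex_map)
        base = ct.detect_contacts(cx, ct.protein_atoms(cx), ct.dna_atoms(cx))
        moved = rigid_transform_structure(cx, seed=8)
        after = ct.detect_contacts(moved, ct.protein_atoms(moved), ct.dna_atoms(moved))
        assert [(e.protein_residue, e.dna_residue, e.contact_class, e.base_specific)
                for e in base] == \
               [(e.protein_residue, e.dna_residue, e.contact_class, e.base_specific)
                for e in after]

    def test_tightening_criteria_never_adds_events(self):
        rng = np.random.default_rng(21)
        loose = ct.ContactCriteria()
        tight = ct.ContactCriteria(hbond_da_max=3.0, hydrophobic_cc_max=4.0,
                                   ionic_max=3.5)
        for _ in range(10):
            cx = random_toy_complex(rng)
            prot, dna = ct.protein_atoms(cx), ct.dna_atoms(cx)
            n_loose = len(ct.detect_contacts(cx, prot, dna, loose))
            n_tight = len(ct.detect_contacts(cx, prot, dna, tight))
            assert n_tight <= n_loose

    def test_empty_selection_rejected(self, toy_duplex):
        with pytest.raises(ArgumentError):
            ct.detect_contacts(toy_duplex, [], ct.dna_atoms(toy_duplex))

    def test_hbond_angle_filter_applies_when_hydrogens_present(self):
        # donor N with an explicit H pointing away from the acceptor: the
        # D-H...A angle is ~0 deg, so no hydrogen bond despite the distance
        dna_o = Atom("O2", "DT", 1, "I", "O", np.array([0.0, 0.0, 0.0]))
        dna_c1 = Atom("C1'", "DT", 1, "I", "C", np.array([0.0, 2.0, 0.0]))
        donor = Atom("ND2", "ASN", 54, "P", "N", np.array([3.0, 0.0, 0.0]))
        h_away = Atom("HD2", "ASN", 54, "P", "H", np.array([4.0, 0.0, 0.0]))
        s = Structure([dna_o, dna_c1, donor, h_away])
        events = ct.detect_contacts(s, [donor, h_away], [dna_o, dna_c1])
        assert not [e for e in events if e.contact_class == "hbond"]
        # flip the hydrogen toward the acceptor -> angle ~180 deg, bond found
        h_toward = Atom("HD2", "ASN", 54, "P", "H", np.array([2.0, 0.0, 0.0]))
        s2 = Structure([dna_o, dna_c1, donor, h_toward])
        events2 = ct.detect_contacts(s2, [donor, h_toward], [dna_o, dna_c1])
        assert [e for e in events2 if e.contact_class == "hbond"]


class TestBarcode:
    def _alternating_trajectory(self, toy_duplex, toy_duplex_map, n_frames=10):
        """Probe contacts the DNA in exactly every other frame."""
        cx = probe_complex(toy_duplex, toy_duplex_map)
        far = []
        for a in cx.atoms:
            if a.chain_id == "P":
                from dataclasses import replace
                far.append(replace(a, position=a.position + np.array([50.0, 0, 0])))
            else:
                far.append(a)
        cx_far = Structure(far)
        frames = [cx if t % 2 == 0 else cx_far for t in range(n_frames)]
        return Trajectory(frames, frame_interval_ns=0.5)

    def test_persistent_contact_has_rate_one(self, toy_duplex, toy_duplex_map):
        cx = probe_complex(toy_duplex, toy_duplex_map)
        traj = Trajectory([cx] * 6, frame_interval_ns=0.5)
        bc = ct.barcode(traj, ct.protein_atoms, ct.dna_atoms,
                        residues_of_interest=(51, 54, 57))
        assert bc.persistence("hbond", True)[bc.residues.index(54)] == 1.0

    def test_half_time_contact_has_rate_half(self, toy_duplex, toy_duplex_map):
        # the analog of a wedge residue touching DNA 50% of simulation time
        traj = self._alternating_trajectory(toy_duplex, toy_duplex_map)
        bc = ct.barcode(traj, ct.protein_atoms, ct.dna_atoms,
                        residues_of_interest=(54, 57))
        assert bc.persistence("hbond", True)[bc.residues.index(54)] == 0.5
        assert bc.persistence("hydrophobic", False)[bc.residues.index(57)] == 0.5

    def test_presence_matrix_matches_designed_pattern(self, toy_duplex, toy_duplex_map):
        traj = self._alternating_trajectory(toy_duplex, toy_duplex_map, n_frames=8)
        bc = ct.barcode(traj, ct.protein_atoms, ct.dna_atoms,
                        residues_of_interest=(54,))
        row = bc.presence[("hbond", True)][0]
        assert row.tolist() == [True, False] * 4

    def test_burn_in_frames_excluded(self, toy_duplex, toy_duplex_map):
        cx = probe_complex(toy_duplex, toy_duplex_map)
        traj = Trajectory([cx] * 10, frame_interval_ns=0.5, burn_in_ns=2.0)
        bc = ct.barcode(traj, ct.protein_atoms, ct.dna_atoms,
                        residues_of_interest=(54,))
        assert bc.presence[("hbond", True)].shape[1] == 6

    def test_single_frame_rates_are_binary(self, toy_duplex, toy_duplex_map):
        cx = probe_complex(toy_duplex, toy_duplex_map)
        traj = Trajectory([cx], frame_interval_ns=0.5)
        bc = ct.barcode(traj, ct.protein_atoms, ct.dna_atoms,
                        residues_of_interest=(51, 54, 57))
        for mat in bc.presence.values():
            assert set(np.unique(mat.mean(axis=1))) <= {0.0, 1.0}

    def test_unknown_residue_of_interest_rejected(self, toy_duplex, toy_duplex_map):
        cx = probe_complex(toy_duplex, toy_duplex_map)
        traj = Trajectory([cx], frame_interval_ns=0.5)
        with pytest.raises(ArgumentError):
            ct.barcode(traj, ct.protein_atoms, ct.dna_atoms,
                       residues_of_interest=(99,))


class TestPersistenceReport:
    def test_zero_barcode_gives_empty_table(self):
        bc = ct.Barcode(residues=[54], frame_indices=[0, 1],
                        presence={(c, b): np.zeros((1, 2), dtype=bool)
                                  for c in ct.CONTACT_CLASSES for b in (False, True)})
        assert ct.persistence_report(bc).empty

    def test_pooled_replicas_equal_frame_weighted_mean(self, toy_duplex, toy_duplex_map):
        cx = probe_complex(toy_duplex, toy_duplex_map)
        t1 = TestBarcode()._alternating_trajectory(toy_duplex, toy_duplex_map, 6)
        t2 = Trajectory([cx] * 4, frame_interval_ns=0.5)
        b1 = ct.barcode(t1, ct.protein_atoms, ct.dna_atoms, residues_of_interest=(54,))
        b2 = ct.barcode(t2, ct.protein_atoms, ct.dna_atoms, residues_of_interest=(54,))
        pooled = np.concatenate([b1.presence[("hbond", True)],
                                 b2.presence[("hbond", True)]], axis=1)
        expected = (6 * b1.persistence("hbond", True) +
                    4 * b2.persistence("hbond", True)) / 10
        assert pooled.mean(axis=1) == pytest.approx(expected)
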