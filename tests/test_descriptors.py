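"""Geometric, counting and interface descriptors on scripted geometries."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gagbind import descriptors as D
from gagbind.descriptors import DescriptorConfig, FEATURE_NAMES
from gagbind.mol_io import Role

from conftest import build_frame, frame_to_trajectory


def _near_frame(distance):
    """One receptor residue whose closest atom sits ``distance`` from the ligand."""
    return build_frame(
        [("CA", "C", "LYS", 1, "RECEPTOR", (0.0, 0.0, 0.0)),
         ("CB", "C", "LYS", 1, "RECEPTOR", (-2.0, 0.0, 0.0)),
         ("C1", "C", "SGU", 9, "LIGAND", (distance, 0.0, 0.0)),
         ("HO1", "H", "SGU", 9, "LIGAND", (distance + 1.0, 0.0, 0.0))]
    )


class TestNearResidues:
    def test_boundary_inside(self):
        assert D.residues_near_ligand(_near_frame(4.9), 5.0) == {1}

    def test_boundary_outside(self):
        assert D.residues_near_ligand(_near_frame(5.1), 5.0) == set()

    def test_monotone_in_radius(self, toy_complex):
        _, traj, _ = toy_complex
        frame = traj.frame(0)
        prev: set = set()
        for radius in (2.0, 4.0, 6.0, 10.0, 20.0):
            current = D.residues_near_ligand(frame, radius)
            assert prev <= current
            prev = current


class TestResidueClassCounts:
    @pytest.fixture
    def charged_frame(self):
        atoms = []
        for rid, (resname, x) in enumerate(
            [("LYS", 0.0), ("LYS", 2.0), ("ASP", 4.0), ("GLY", 6.0), ("HIE", 30.0)],
            start=1,
        ):
            atoms.append(("CA", "C", resname, rid, "RECEPTOR", (x, 3.0, 0.0)))
        atoms.append(("C1", "C", "SGU", 99, "LIGAND", (2.0, 0.0, 0.0)))
        atoms.append(("HO1", "H", "SGU", 99, "LIGAND", (2.0, -1.0, 0.0)))
        return build_frame(atoms)

    def test_two_lys_one_asp(self, charged_frame):
        n_pos, n_neg, net = D.charged_counts(charged_frame, 5.0)
        assert (n_pos, n_neg, net) == (2, 1, 1)

    def test_empty_neighborhood(self, charged_frame):
        assert D.charged_counts(charged_frame, 0.5) == (0, 0, 0)

    def test_hie_counts_positive(self):
        frame = build_frame(
            [("CA", "C", "HIE", 1, "RECEPTOR", (0, 0, 0)),
             ("C1", "C", "SGU", 2, "LIGAND", (3, 0, 0))]
        )
        assert D.charged_counts(frame, 5.0)[0] == 1

    def test_gly_in_neither_polarity_class(self, charged_frame):
        n_phob, n_phil, polarity = D.polarity_counts(charged_frame, 10.0)
        # LYS, LYS, ASP hydrophilic; GLY unclassified; HIE out of range
        assert (n_phob, n_phil, polarity) == (0, 3, 3)


class TestLigandGeometry:
    def test_eed_345_triangle(self):
        frame = build_frame(
            [("CA", "C", "GLY", 1, "RECEPTOR", (9, 9, 9)),
             ("C1", "C", "SGU", 2, "LIGAND", (0, 0, 0)),
             ("O1", "O", "SGU", 2, "LIGAND", (1, 1, 0)),
             ("C1", "C", "SGU", 3, "LIGAND", (3, 4, 0))]
        )
        assert D.end_to_end_distance(frame) == pytest.approx(5.0)

    def test_eed_coincident_anchors(self):
        frame = build_frame(
            [("C1", "C", "SGU", 1, "LIGAND", (1, 1, 1)),
             ("C2", "C", "SGU", 1, "LIGAND", (1, 1, 1))]
        )
        assert D.end_to_end_distance(frame) == 0.0

    def test_eed_single_atom_rejected(self):
        frame = build_frame([("C1", "C", "SGU", 1, "LIGAND", (0, 0, 0))])
        with pytest.raises(ValueError):
            D.end_to_end_distance(frame)

    def test_radgyr_dumbbell(self):
        frame = build_frame(
            [("C1", "C", "SGU", 1, "LIGAND", (1, 0, 0), 0.0, 1.0),
             ("C2", "C", "SGU", 1, "LIGAND", (-1, 0, 0), 0.0, 1.0)]
        )
        assert D.radius_of_gyration(frame) == pytest.approx(1.0)

    def test_radgyr_unit_square(self):
        frame = build_frame(
            [("C1", "C", "SGU", 1, "LIGAND", (0, 0, 0), 0.0, 1.0),
             ("C2", "C", "SGU", 1, "LIGAND", (1, 0, 0), 0.0, 1.0),
             ("C3", "C", "SGU", 1, "LIGAND", (1, 1, 0), 0.0, 1.0),
             ("C4", "C", "SGU", 1, "LIGAND", (0, 1, 0), 0.0, 1.0)]
        )
        assert D.radius_of_gyration(frame) == pytest.approx(np.sqrt(2) / 2, abs=1e-6)

    def test_radgyr_point_mass(self):
        frame = build_frame(
            [("C1", "C", "SGU", 1, "LIGAND", (2, 2, 2)),
             ("C2", "C", "SGU", 1, "LIGAND", (2, 2, 2))]
        )
        assert D.radius_of_gyration(frame) == 0.0

    def test_com_distance(self):
        frame = build_frame(
            [("CA", "C", "GLY", 1, "RECEPTOR", (0, 0, 0)),
             ("C1", "C", "SGU", 2, "LIGAND", (0, 0, 10))]
        )
        assert D.com_distance(frame) == pytest.approx(10.0)


def _two_rods(direction_l):
    atoms = []
    for i in range(4):
        atoms.append(("CA", "C", "GLY", 1, "RECEPTOR", (float(i), 0.0, 0.0)))
    for i in range(4):
        pos = tuple(float(i) * np.asarray(direction_l) + np.array([0.0, 8.0, 0.0]))
        atoms.append(("C1", "C", "SGU", 2, "LIGAND", pos))
    return build_frame(atoms)


class TestOrientationAngle:
    def test_orthogonal_rods(self):
        assert D.orientation_angle(_two_rods((0, 1, 0))) == pytest.approx(90.0)

    def test_parallel_rods(self):
        assert D.orientation_angle(_two_rods((1, 0, 0))) == pytest.approx(0.0, abs=1e-6)

    def test_antiparallel_folds_to_zero(self):
        assert D.orientation_angle(_two_rods((-1, 0, 0))) == pytest.approx(0.0, abs=1e-6)

    def test_coincident_geometry_flagged_nan(self):
        frame = build_frame(
            [("CA", "C", "GLY", 1, "RECEPTOR", (0, 0, 0)),
             ("CB", "C", "GLY", 1, "RECEPTOR", (0, 0, 0)),
             ("C1", "C", "SGU", 2, "LIGAND", (5, 0, 0)),
             ("C2", "C", "SGU", 2, "LIGAND", (6, 0, 0))]
        )
        assert np.isnan(D.orientation_angle(frame))


class TestContacts:
    @pytest.fixture
    def contact_frame(self):
        return build_frame(
            [("CA", "C", "GLY", 1, "RECEPTOR", (0, 0, 0)),
             ("CA", "C", "GLY", 2, "RECEPTOR", (3, 0, 0)),
             ("CA", "C", "GLY", 3, "RECEPTOR", (6, 0, 0)),
             ("C1", "C", "SGU", 9, "LIGAND", (0, 0, 3))]
        )

    def test_short_cutoff(self, contact_frame):
        # brute-force pair distances: 3.00, 4.24, 6.71
        assert D.count_contacts(contact_frame, 3.5) == 1

    def test_medium_cutoff(self, contact_frame):
        assert D.count_contacts(contact_frame, 5.0) == 2

    def test_far_ligand(self):
        frame = build_frame(
            [("CA", "C", "GLY", 1, "RECEPTOR", (0, 0, 0)),
             ("C1", "C", "SGU", 2, "LIGAND", (50, 50, 50))]
        )
        assert D.count_contacts(frame, 3.5) == 0
        assert D.count_contacts(frame, 5.0) == 0

    def test_hydrogens_excluded(self):
        frame = build_frame(
            [("CA", "C", "GLY", 1, "RECEPTOR", (0, 0, 0)),
             ("HA", "H", "GLY", 1, "RECEPTOR", (1, 0, 0)),
             ("C1", "C", "SGU", 2, "LIGAND", (2.0, 0, 0))]
        )
        assert D.count_contacts(frame, 3.5) == 1  # only the heavy-heavy pair

    def test_monotone_in_cutoff(self, toy_complex):
        _, traj, _ = toy_complex
        counts = [D.count_contacts(traj.frame(0), c) for c in (2.0, 3.5, 5.0, 8.0)]
        assert counts == sorted(counts)


class TestHydrogenBonds:
    def _triad(self, acceptor_pos, donor_is_ligand=True):
        role_d = "LIGAND" if donor_is_ligand else "RECEPTOR"
        role_a = "RECEPTOR" if donor_is_ligand else "LIGAND"
        resname_d = "SGU" if donor_is_ligand else "SER"
        resname_a = "SER" if donor_is_ligand else "SGU"
        return build_frame(
            [("O1", "O", resname_d, 1, role_d, (0.0, 0.0, 0.0)),
             ("HO1", "H", resname_d, 1, role_d, (1.0, 0.0, 0.0)),
             ("OG", "O", resname_a, 2, role_a, acceptor_pos)]
        )

    def test_linear_geometry_counts(self):
        frame = self._triad((2.8, 0.0, 0.0))
        assert D.count_hbonds(frame, ligand_is_donor=True) == 1
        assert D.count_hbonds(frame, ligand_is_donor=False) == 0

    def test_right_angle_fails(self):
        # donor-H-acceptor angle 90 degrees at short D-A distance
        frame = self._triad((1.0, 1.8, 0.0))
        assert D.count_hbonds(frame, ligand_is_donor=True) == 0

    def test_distance_cutoff_fails(self):
        frame = self._triad((3.6, 0.0, 0.0))
        assert D.count_hbonds(frame, ligand_is_donor=True) == 0

    def test_receptor_donor_direction(self):
        frame = self._triad((2.8, 0.0, 0.0), donor_is_ligand=False)
        assert D.count_hbonds(frame, ligand_is_donor=False) == 1
        assert D.count_hbonds(frame, ligand_is_donor=True) == 0

    def test_hbond_pairs_are_short_contacts(self, toy_complex):
        _, traj, _ = toy_complex
        frame = traj.frame(0)
        total_hb = D.count_hbonds(frame, True) + D.count_hbonds(frame, False)
        assert total_hb > 0  # the generator scripts at least one bond each way
        assert total_hb <= D.count_contacts(frame, 3.5)


class TestRMSDProfile:
    def _base(self):
        return build_frame(
            [("CA", "C", "GLY", 1, "RECEPTOR", (0, 0, 0)),
             ("CA", "C", "GLY", 2, "RECEPTOR", (3, 0, 0)),
             ("CA", "C", "GLY", 3, "RECEPTOR", (0, 3, 0)),
             ("C1", "C", "SGU", 9, "LIGAND", (0, 0, 5)),
             ("C2", "C", "SGU", 9, "LIGAND", (1, 0, 5))]
        )

    def _traj_with_shift(self, shift):
        base = self._base()
        moved = base.coords.copy()
        moved[3:] += shift
        traj = frame_to_trajectory([base, base])
        traj.coords[1] = moved
        return traj

    def test_identical_frames_zero(self):
        traj = frame_to_trajectory([self._base(), self._base()])
        profile = D.rmsd_profile([traj])
        assert np.allclose(profile["rmsd_mean"], 0.0)

    def test_rigid_ligand_translation(self):
        traj = self._traj_with_shift(np.array([0.0, 0.0, 5.0]))
        profile = D.rmsd_profile([traj])
        assert profile["rmsd_mean"].iloc[1] == pytest.approx(5.0, abs=1e-6)

    def test_mean_and_population_std_across_trajectories(self):
        t1 = self._traj_with_shift(np.array([0.0, 0.0, 4.0]))
        t2 = self._traj_with_shift(np.array([0.0, 0.0, 6.0]))
        profile = D.rmsd_profile([t1, t2])
        assert profile["rmsd_mean"].iloc[1] == pytest.approx(5.0, abs=1e-6)
        assert profile["rmsd_std"].iloc[1] == pytest.approx(1.0, abs=1e-6)

    def test_unequal_lengths_truncate_with_warning(self):
        t1 = frame_to_trajectory([self._base(), self._base(), self._base()])
        t2 = frame_to_trajectory([self._base(), self._base()])
        with pytest.warns(UserWarning, match="truncating"):
            profile = D.rmsd_profile([t1, t2])
        assert len(profile) == 2


class TestFeatureVector:
    def test_deterministic(self, toy_complex):
        _, traj, _ = toy_complex
        v1 = D.compute_feature_vector(traj.frame(0))
        v2 = D.compute_feature_vector(traj.frame(0))
        assert (v1 == v2).all()

    def test_canonical_order_and_size(self, toy_complex):
        _, traj, _ = toy_complex
        vec = D.compute_feature_vector(traj.frame(0))
        assert tuple(vec.index) == FEATURE_NAMES
        assert len(vec) == 25

    def test_dissociated_ligand_empty_interface(self):
        from gagbind.synthetic import ToyComplexSpec, gen_toy_complex

        spec = ToyComplexSpec(seed=3, com_offset=60.0, script_hbonds=False)
        traj, _ = gen_toy_complex(spec)
        vec = D.compute_feature_vector(traj.frame(0))
        for name in ("n_pos_5A", "n_neg_5A", "n_phobic_10A", "n_philic_10A",
                     "n_contacts_short", "n_contacts_medium",
                     "n_hbonds_gag_donor", "n_hbonds_gag_acceptor"):
            assert vec[name] == 0

    def test_derived_identities(self, toy_complex):
        _, traj, _ = toy_complex
        vec = D.compute_feature_vector(traj.frame(0))
        assert vec["net_charge_5A"] == vec["n_pos_5A"] - vec["n_neg_5A"]
        assert vec["polarity_5A"] == vec["n_philic_5A"] - vec["n_phobic_5A"]
        assert vec["polarity_10A"] == vec["n_philic_10A"] - vec["n_phobic_10A"]
        assert vec["n_contacts_short"] <= vec["n_contacts_medium"]

    def test_rigid_body_invariance(self, toy_complex):
        _, traj, _ = toy_complex
        frame = traj.frame(0)
        rot = Rotation.from_euler("xyz", [20, -35, 110], degrees=True)
        moved = D.ComplexFrame(frame.topology, rot.apply(frame.coords) + np.array([5.0, -3.0, 8.0]))
        ref = D.compute_feature_vector(frame)
        new = D.compute_feature_vector(moved)
        sasa = ("sasa_prot", "sasa_gag", "sasa_complex")
        for name in ref.index:
            if name in sasa:
                # the point lattice is fixed in space, so rotation changes the
                # occlusion pattern slightly; areas agree to well under 1%
                assert new[name] == pytest.approx(ref[name], rel=0.01)
            else:
                assert new[name] == pytest.approx(ref[name], rel=1e-8, abs=1e-8)

    def test_feature_subset_config(self, toy_complex):
        _, traj, _ = toy_complex
        cfg = DescriptorConfig(feature_set=tuple(f for f in FEATURE_NAMES if f != "sasa_prot"))
        vec = D.compute_feature_vector(traj.frame(0), cfg)
        assert len(vec) == 24 and "sasa_prot" not in vec.index

    def test_extract_table_schema(self, toy_complex):
        _, traj, _ = toy_complex
        df = D.extract_feature_table(traj)
        assert len(df) == traj.n_frames
        assert list(df["frame_index"]) == list(range(traj.n_frames))
        for col in ("system_id", "protein_id", "gag_type", "gag_length", "pose"):
            assert col in df.columns
        for name in FEATURE_NAMES:
            assert name in df.columns
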