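"""Feature primitives, rigid-motion invariance, and reactive-like criteria."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tisdesign.geometry import (CriterionReport, FeatureDef, FeatureSchema,
                                UndefinedGeometryError, angle, axis_angle,
                                compute_features, compute_lambda,
                                criterion_population, dihedral, distance,
                                evaluate_criteria, min_dihedral)


class TestLambda:
    def test_arithmetic(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 0, 5], [0, 1.5, 5]])
        assert compute_lambda(frame, (0, 1), (2, 3)) == pytest.approx(0.5)

    def test_symmetric_geometry_zero(self):
        frame = np.array([[1.7, 0, 0], [0, 0, 0], [-1.7, 0, 0]])
        assert compute_lambda(frame, (0, 1), (1, 2)) == pytest.approx(0.0)

    def test_swap_negates(self, rng):
        frame = rng.normal(size=(4, 3))
        a = compute_lambda(frame, (0, 1), (2, 3))
        b = compute_lambda(frame, (2, 3), (0, 1))
        assert a == pytest.approx(-b)

    def test_coincident_atoms_error(self):
        frame = np.zeros((3, 3))
        with pytest.raises(UndefinedGeometryError):
            compute_lambda(frame, (0, 1), (1, 2))


class TestPrimitives:
    def test_orthogonal_angle(self):
        frame = np.array([[1.0, 0, 0], [0, 0, 0], [0, 1.0, 0]])
        assert angle(frame, 0, 1, 2) == pytest.approx(90.0)

    def test_planar_cis_dihedral_zero(self):
        frame = np.array([[0, 1.0, 0], [0, 0, 0], [1.0, 0, 0], [1.0, 1.0, 0]])
        assert dihedral(frame, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-9)

    def test_trans_dihedral_180(self):
        frame = np.array([[0, 1.0, 0], [0, 0, 0], [1.0, 0, 0], [1.0, -1.0, 0]])
        assert dihedral(frame, 0, 1, 2, 3) == pytest.approx(180.0)

    def test_signed_mode_keeps_sign(self):
        frame = np.array([[0, 1.0, 0], [0, 0, 0], [1.0, 0, 0], [1.0, 0.5, 0.7]])
        s = dihedral(frame, 0, 1, 2, 3, signed=True)
        assert dihedral(frame, 0, 1, 2, 3) == pytest.approx(abs(s))

    def test_min_dihedral_of_constructed_hydrogens(self):
        """H placed at torsion 0 and torsion ~120: the minimum is the
        eclipsed one."""
        frame = np.array([
            [0, 1.0, 0],            # i
            [0, 0, 0],              # j
            [1.0, 0, 0],            # k
            [1.0, 1.0, 0],          # H at 0 deg
            [1.0, np.cos(np.radians(120)), np.sin(np.radians(120))],  # ~120
        ])
        assert min_dihedral(frame, 0, 1, 2, [3, 4]) == pytest.approx(0.0, abs=1e-9)
        assert min_dihedral(frame, 0, 1, 2, [4]) == pytest.approx(120.0)

    def test_min_dihedral_bounded_by_members(self, rng):
        frame = rng.normal(size=(7, 3))
        h_set = [3, 4, 5, 6]
        m = min_dihedral(frame, 0, 1, 2, h_set)
        for h in h_set:
            assert m <= dihedral(frame, 0, 1, 2, h) + 1e-12

    def test_collinear_angle_error(self):
        frame = np.array([[1.0, 0, 0], [0, 0, 0], [0, 0, 0]])
        with pytest.raises(UndefinedGeometryError):
            angle(frame, 0, 1, 2)

    def test_axis_angle_folded(self):
        frame = np.array([[0, 0, 0], [1.0, 0, 0], [0, 0, 1.0],
                          [-1.0, 0.001, 1.0]])
        # near-antiparallel axes fold to ~0 (undirected convention)
        assert axis_angle(frame, (0, 1), (2, 3)) < 1.0


def test_rigid_transform_invariance(rng):
    """Distances/angles/dihedrals are invariant under random rotations and
    translations to 1e-9."""
    schema = FeatureSchema([
        FeatureDef("d01", "distance", (0, 1)),
        FeatureDef("a012", "angle", (0, 1, 2)),
        FeatureDef("t0123", "dihedral", (0, 1, 2, 3)),
        FeatureDef("m012", "min_dihedral", (0, 1, 2), h_set=(3, 4, 5)),
    ])
    for _ in range(25):
        frame = rng.normal(size=(6, 3)) * 2.0
        base = compute_features(frame, schema)
        rot = Rotation.random(random_state=rng.integers(2 ** 31)).as_matrix()
        shift = rng.normal(size=3) * 10
        moved = frame @ rot.T + shift
        assert np.max(np.abs(compute_features(moved, schema) - base)) < 1e-9


class TestCriteria:
    def _hbond_frame(self, dist, donor_angle=180.0, acceptor_angle=120.0):
        """Donor N, H, acceptor O, carbonyl C laid out in a plane with the
        requested H...O distance and angles."""
        h = np.array([0.0, 0.0, 0.0])
        n = np.array([-1.0, 0.0, 0.0])
        # place O such that angle N-H-O equals donor_angle
        th = np.radians(180.0 - donor_angle)
        o = h + dist * np.array([np.cos(th), np.sin(th), 0.0])
        # place C so that angle H-O-C equals acceptor_angle
        u = (h - o) / np.linalg.norm(h - o)
        phi = np.radians(acceptor_angle)
        rot = np.array([[np.cos(phi), -np.sin(phi), 0],
                        [np.sin(phi), np.cos(phi), 0], [0, 0, 1.0]])
        c = o + 1.23 * (rot @ u)
        return np.stack([n, h, o, c])

    ROLES = {"donor_heavy": 0, "donor_h": 1, "acceptor": 2,
             "acceptor_antecedent": 3}

    def test_hbond_strict_distance_boundary(self):
        at = evaluate_criteria(self._hbond_frame(2.3), self.ROLES)
        below = evaluate_criteria(self._hbond_frame(2.29), self.ROLES)
        assert at.hbond_present is False      # exactly 2.3 A fails (strict <)
        assert below.hbond_present is True

    def test_hbond_angle_windows(self):
        good = evaluate_criteria(self._hbond_frame(2.0, 160.0, 100.0),
                                 self.ROLES)
        bad_donor = evaluate_criteria(self._hbond_frame(2.0, 149.0, 120.0),
                                      self.ROLES)
        bad_acceptor = evaluate_criteria(self._hbond_frame(2.0, 180.0, 155.0),
                                         self.ROLES)
        assert good.hbond_present is True
        assert bad_donor.hbond_present is False
        assert bad_acceptor.hbond_present is False

    def test_hbond_monotone_in_distance(self):
        """Shrinking the distance with angles fixed never turns a present
        bond absent."""
        present = False
        for d in np.linspace(2.5, 0.8, 18):
            rep = evaluate_criteria(self._hbond_frame(d), self.ROLES)
            if present:
                assert rep.hbond_present
            present = present or rep.hbond_present
        assert present

    @staticmethod
    def _axis_frame(angle_deg):
        a = np.radians(angle_deg)
        return np.array([[0, 0, 0], [1.0, 0, 0],
                         [0, 0, 1.0], [np.cos(a), np.sin(a), 1.0]])

    def test_rotated_strict_boundary(self):
        roles = {"rotated_axis1": (0, 1), "rotated_axis2": (2, 3)}
        assert evaluate_criteria(self._axis_frame(74.9), roles).rotated is True
        assert evaluate_criteria(self._axis_frame(75.0), roles).rotated is False
        assert evaluate_criteria(self._axis_frame(75.1), roles).rotated is False

    @staticmethod
    def _eclipse_frame(torsion_deg):
        t = np.radians(torsion_deg)
        return np.array([[0, 1.0, 0], [0, 0, 0], [1.0, 0, 0],
                         [1.0, np.cos(t), np.sin(t)]])

    def test_eclipsed_strict_boundary(self):
        roles = {"eclipsed_quads": [(0, 1, 2, (3,))]}
        assert evaluate_criteria(self._eclipse_frame(29.0), roles).eclipsed is True
        assert evaluate_criteria(self._eclipse_frame(31.0), roles).eclipsed is False

    def test_missing_roles_report_none(self):
        rep = evaluate_criteria(np.zeros((2, 3)) + np.arange(2)[:, None], {})
        assert rep.hbond_present is None
        assert rep.rotated is None
        assert rep.eclipsed is None


class TestCriterionPopulation:
    ROLES = {"eclipsed_quads": [(0, 1, 2, (3,))]}

    def _frames(self, torsions):
        t = np.radians(np.asarray(torsions, dtype=float))
        f = np.zeros((len(t), 4, 3))
        f[:, 0] = (0, 1.0, 0)
        f[:, 2] = (1.0, 0, 0)
        f[:, 3, 0] = 1.0
        f[:, 3, 1] = np.cos(t)
        f[:, 3, 2] = np.sin(t)
        return f

    def test_all_satisfy_gives_one(self):
        pop = criterion_population(self._frames([5, 10, 15]), self.ROLES)
        assert pop["eclipsed"] == pytest.approx(1.0)

    def test_weighted_mean(self):
        pop = criterion_population(self._frames([10, 60]), self.ROLES,
                                   weights=[3, 1])
        assert pop["eclipsed"] == pytest.approx(0.75)

    def test_reference_normalization_identity(self):
        frames = self._frames([10, 60, 20])
        pop = criterion_population(frames, self.ROLES)
        norm = criterion_population(frames, self.ROLES, reference=pop)
        assert norm["eclipsed_normalized"] == pytest.approx(1.0)

    def test_zero_weight_error(self):
        with pytest.raises(ValueError):
            criterion_population(self._frames([10]), self.ROLES, weights=[0.0])


def test_schema_yaml_roundtrip_and_unique_names():
    schema = FeatureSchema([
        FeatureDef("d", "distance", (0, 1)),
        FeatureDef("m", "min_dihedral", (2, 3, 4), h_set=(5, 6)),
    ])
    clone = FeatureSchema.from_yaml(schema.to_yaml())
    assert clone.names == schema.names
    assert clone.features[1].h_set == (5, 6)
    with pytest.raises(ValueError):
        FeatureSchema([FeatureDef("x", "distance", (0, 1)),
                       FeatureDef("x", "distance", (1, 2))])


def test_pdb_coordinates_roundtrip(tmp_path):
    """Minimal PDB: coordinates and 1-based residue numbering preserved."""
    pdb = "\n".join([
        "ATOM      1  N   ALA A   7      11.104   6.134  -6.504  1.00  0.00           N",
        "ATOM      2  CA  ALA A   7      11.639   6.071  -5.147  1.00  0.00           C",
        "ATOM      3  C   GLY A   8      12.685   7.147  -4.874  1.00  0.00           C",
        "END",
    ]) + "\n"
    path = tmp_path / "mini.pdb"
    path.write_text(pdb)
    from tisdesign.geometry import read_pdb_coordinates
    coords, table = read_pdb_coordinates(path)
    assert coords.shape == (3, 3)
    assert coords[0, 0] == pytest.approx(11.104, abs=1e-3)
    assert table.resseq.tolist() == [7, 7, 8]
    assert table.name.tolist() == ["N", "CA", "C"]
    assert distance(coords, 0, 1) == pytest.approx(
        np.linalg.norm(coords[0] - coords[1]))
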