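"""Coordinate parsing, donor/acceptor distances and superposition."""

import itertools
import math

import gemmi
import numpy as np
import pytest

from vsdflex.structure_geometry import (
    Atom,
    SelectionError,
    StructureFormatError,
    StructureModel,
    detect_salt_bridges,
    donor_acceptor_atoms,
    min_pair_distance,
    read_structure,
    superpose_motif,
)
from vsdflex.synthetic_data import ToyStructureSpec, generate_toy_structure

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00 10.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00 10.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C
ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60 10.00           C
END
"""


def _model_from_atoms(atoms):
    return StructureModel(atoms=tuple(atoms))


def _atom(chain, res_name, res_seq, name, xyz):
    return Atom(
        chain=chain,
        res_name=res_name,
        res_seq=res_seq,
        atom_name=name,
        element=name[0],
        pos=tuple(float(v) for v in xyz),
    )


class TestReadStructure:
    def test_toy_pdb_exact_coordinates(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(TOY_PDB)
        model = read_structure(path)
        assert len(model.atoms) == 3
        ca = next(a for a in model.atoms if a.atom_name == "CA")
        assert ca.pos == pytest.approx((1.5, 0.0, 0.0))

    def test_mmcif_matches_pdb(self, tmp_path):
        pdb_path = tmp_path / "toy.pdb"
        pdb_path.write_text(TOY_PDB)
        st = gemmi.read_pdb(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "toy.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        a = read_structure(pdb_path)
        b = read_structure(cif_path)
        assert {(x.atom_name, x.pos) for x in a.atoms} == {
            (x.atom_name, x.pos) for x in b.atoms
        }

    def test_altloc_retains_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        model = read_structure(path)
        assert len(model.atoms) == 1
        assert model.atoms[0].pos[0] == pytest.approx(5.0)

    def test_unparseable_file_raises_format_error(self, tmp_path):
        path = tmp_path / "junk.cif"
        path.write_text("this is not a structure")
        with pytest.raises(StructureFormatError):
            read_structure(path, format="mmcif")


class TestDonorAcceptorAtoms:
    def test_lysine_donor(self):
        assert donor_acceptor_atoms("LYS") == ("NZ",)

    def test_arginine_guanidinium_nitrogens(self):
        assert donor_acceptor_atoms("ARG") == ("NE", "NH1", "NH2")

    def test_aspartate_carboxyl_oxygens(self):
        assert donor_acceptor_atoms("ASP") == ("OD1", "OD2")

    def test_glutamate_carboxyl_oxygens(self):
        assert donor_acceptor_atoms("GLU") == ("OE1", "OE2")

    def test_other_residue_rejected(self):
        with pytest.raises(ValueError):
            donor_acceptor_atoms("GLY")


class TestMinPairDistance:
    def test_three_four_five(self):
        model = _model_from_atoms(
            [
                _atom("A", "GLY", 1, "CA", (0, 0, 0)),
                _atom("A", "GLY", 2, "CA", (3, 4, 0)),
            ]
        )
        d = min_pair_distance(model, ("A", 1, None), ("A", 2, None))
        assert d == pytest.approx(5.0)

    def test_equals_brute_force_minimum(self, rng):
        atoms = []
        for res_seq, res in ((1, "GLY"), (2, "GLY")):
            for i in range(4):
                atoms.append(
                    _atom("A", res, res_seq, f"C{i}", rng.uniform(-5, 5, 3))
                )
        model = _model_from_atoms(atoms)
        expected = min(
            np.linalg.norm(a.xyz - b.xyz)
            for a in atoms[:4]
            for b in atoms[4:]
        )
        d = min_pair_distance(model, ("A", 1, None), ("A", 2, None))
        assert d == pytest.approx(expected)

    def test_symmetric_in_argument_order(self, rng):
        atoms = [
            _atom("A", "LYS", 1, "NZ", (0, 0, 0)),
            _atom("A", "ASP", 2, "OD1", (2, 2, 1)),
            _atom("A", "ASP", 2, "OD2", (3, 1, 0)),
        ]
        model = _model_from_atoms(atoms)
        ab = min_pair_distance(model, ("A", 1, None), ("A", 2, None))
        ba = min_pair_distance(model, ("A", 2, None), ("A", 1, None))
        assert ab == pytest.approx(ba)

    def test_ambiguous_selector_rejected(self):
        atoms = [
            _atom("A", "GLY", 1, "CA", (0, 0, 0)),
            _atom("B", "ALA", 1, "CA", (1, 0, 0)),
            _atom("A", "GLY", 2, "CA", (2, 0, 0)),
        ]
        model = _model_from_atoms(atoms)
        with pytest.raises(SelectionError):
            min_pair_distance(model, ("A", 3, None), ("A", 2, None))


class TestSaltBridges:
    def _lys_asp_model(self, od1_x):
        return _model_from_atoms(
            [
                _atom("A", "LYS", 1, "NZ", (0, 0, 0)),
                _atom("A", "LYS", 1, "CE", (-1.5, 0, 0)),
                _atom("A", "ASP", 2, "OD1", (od1_x, 0, 0)),
                _atom("A", "ASP", 2, "OD2", (od1_x + 1, 1.8, 0)),
            ]
        )

    def test_bridge_inside_cutoff(self):
        records = detect_salt_bridges(
            self._lys_asp_model(3.5), [("A", 1, None)], [("A", 2, None)]
        )
        nz_od1 = next(r for r in records if r.acceptor_atom == "OD1")
        assert nz_od1.distance == pytest.approx(3.5)
        assert nz_od1.is_bridge

    def test_cutoff_is_inclusive(self):
        records = detect_salt_bridges(
            self._lys_asp_model(4.0), [("A", 1, None)], [("A", 2, None)]
        )
        nz_od1 = next(r for r in records if r.acceptor_atom == "OD1")
        assert nz_od1.is_bridge

    def test_just_outside_cutoff_is_not_a_bridge(self):
        records = detect_salt_bridges(
            self._lys_asp_model(4.001), [("A", 1, None)], [("A", 2, None)]
        )
        nz_od1 = next(r for r in records if r.acceptor_atom == "OD1")
        assert not nz_od1.is_bridge

    def test_equals_all_pairs_brute_force(self, rng):
        # Arg donor against Glu acceptor with randomized atom positions
        atoms = []
        for name in ("NE", "NH1", "NH2", "CZ"):
            atoms.append(_atom("A", "ARG", 1, name, rng.uniform(-3, 3, 3)))
        for name in ("OE1", "OE2", "CD"):
            atoms.append(_atom("A", "GLU", 2, name, rng.uniform(0, 6, 3)))
        model = _model_from_atoms(atoms)
        records = detect_salt_bridges(model, [("A", 1, None)], [("A", 2, None)])
        donors = [a for a in atoms if a.atom_name in ("NE", "NH1", "NH2")]
        acceptors = [a for a in atoms if a.atom_name in ("OE1", "OE2")]
        expected = {
            (d.atom_name, a.atom_name): float(np.linalg.norm(d.xyz - a.xyz))
            for d in donors
            for a in acceptors
        }
        got = {(r.donor_atom, r.acceptor_atom): r.distance for r in records}
        assert got == pytest.approx(expected)
        for r in records:
            assert r.is_bridge == (r.distance <= 4.0)

    def test_non_donor_residue_rejected(self):
        model = _model_from_atoms([_atom("A", "GLY", 1, "CA", (0, 0, 0))])
        with pytest.raises(ValueError):
            detect_salt_bridges(model, [("A", 1, None)], [("A", 1, None)])


def _ca_model(points, chain="A"):
    return _model_from_atoms(
        [_atom(chain, "GLY", i + 1, "CA", p) for i, p in enumerate(points)]
    )


def _rigid_transform(points, rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    shift = rng.uniform(-20, 20, 3)
    return points @ rot.T + shift


def quaternion_rmsd(pts_a, pts_b):
    """Independent oracle: Horn's quaternion method for optimal RMSD."""
    a = pts_a - pts_a.mean(axis=0)
    b = pts_b - pts_b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = float(np.sum(a ** 2) + np.sum(b ** 2))
    return math.sqrt(max(0.0, e0 - 2.0 * lam) / len(a))


class TestSuperposition:
    def _pairs(self, n):
        return [(("A", i + 1, None), ("A", i + 1, None)) for i in range(n)]

    def test_identical_models_give_zero(self, rng):
        pts = rng.uniform(-10, 10, (5, 3))
        model = _ca_model(pts)
        assert superpose_motif(model, model, self._pairs(5)) == pytest.approx(0.0, abs=1e-9)

    def test_rigidly_moved_copy_gives_zero(self, rng):
        pts = rng.uniform(-10, 10, (6, 3))
        moved = _rigid_transform(pts, rng)
        rmsd = superpose_motif(_ca_model(pts), _ca_model(moved), self._pairs(6))
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(10):
            pts_a = rng.uniform(-10, 10, (5, 3))
            pts_b = rng.uniform(-10, 10, (5, 3))
            rmsd = superpose_motif(_ca_model(pts_a), _ca_model(pts_b), self._pairs(5))
            assert rmsd == pytest.approx(quaternion_rmsd(pts_a, pts_b), abs=1e-6)

    def test_invariant_under_rigid_motion_of_either_model(self, rng):
        pts_a = rng.uniform(-10, 10, (5, 3))
        pts_b = rng.uniform(-10, 10, (5, 3))
        base = superpose_motif(_ca_model(pts_a), _ca_model(pts_b), self._pairs(5))
        moved_a = superpose_motif(
            _ca_model(_rigid_transform(pts_a, rng)), _ca_model(pts_b), self._pairs(5)
        )
        moved_b = superpose_motif(
            _ca_model(pts_a), _ca_model(_rigid_transform(pts_b, rng)), self._pairs(5)
        )
        assert moved_a == pytest.approx(base, abs=1e-9)
        assert moved_b == pytest.approx(base, abs=1e-9)

    def test_fewer_than_three_pairs_rejected(self, rng):
        model = _ca_model(rng.uniform(-1, 1, (3, 3)))
        with pytest.raises(ValueError):
            superpose_motif(model, model, self._pairs(2))
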