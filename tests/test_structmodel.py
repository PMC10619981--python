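"""Structure I/O and rigid-body geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kinfold.errors import (
    DegenerateGeometryError,
    EmptyStructureError,
    FormatError,
    SiteLookupError,
)
from kinfold.structmodel import (
    AtomRecord,
    RigidTransform,
    StructureModel,
    ca_rmsd,
    clash_count,
    dimer_rmsd,
    end_to_end_length,
    read_structure,
    superpose,
    write_structure,
)

from conftest import ideal_helix


def two_chain_model(n=30):
    atoms = []
    trace = ideal_helix(n)
    for chain, offset in (("A", 0.0), ("B", 10.0)):
        for i, xyz in enumerate(trace, start=1):
            atoms.append(
                AtomRecord(chain, i, "ALA", "CA", xyz + np.array([0, offset, 0]))
            )
    return StructureModel(atoms)


class TestAtomRecord:
    def test_rejects_nonfinite_position(self):
        with pytest.raises(ValueError):
            AtomRecord("A", 1, "ALA", "CA", np.array([np.nan, 0, 0]))

    def test_rejects_zero_residue_number(self):
        with pytest.raises(ValueError):
            AtomRecord("A", 0, "ALA", "CA", np.zeros(3))


class TestRigidTransform:
    def test_rejects_reflection(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_and_inverse(self, rng):
        a = RigidTransform(
            Rotation.random(random_state=1).as_matrix(), rng.normal(size=3)
        )
        b = RigidTransform(
            Rotation.random(random_state=2).as_matrix(), rng.normal(size=3)
        )
        pts = rng.normal(size=(5, 3))
        np.testing.assert_allclose(
            a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-12
        )
        np.testing.assert_allclose(
            a.inverse().apply(a.apply(pts)), pts, atol=1e-12
        )


class TestIO:
    def test_round_trip_pdb_and_mmcif(self, tmp_path):
        model = two_chain_model(100)
        for fmt, name in (("pdb", "m.pdb"), ("mmcif", "m.cif")):
            path = tmp_path / name
            write_structure(model, path, fmt)
            back = read_structure(path, fmt)
            assert len(back) == len(model)
            assert np.abs(back.coords - model.coords).max() <= 1e-3

    def test_pdb_and_mmcif_agree(self, tmp_path):
        model = two_chain_model(50)
        write_structure(model, tmp_path / "m.pdb", "pdb")
        write_structure(model, tmp_path / "m.cif", "mmcif")
        a = read_structure(tmp_path / "m.pdb", "auto")
        b = read_structure(tmp_path / "m.cif", "auto")
        assert np.abs(a.coords - b.coords).max() <= 1e-3

    def test_minimal_two_atom_pdb(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       4.000   5.000   6.000  1.00  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "mini.pdb"
        p.write_text(text)
        m = read_structure(p)
        assert len(m) == 2
        np.testing.assert_allclose(m.position(("A", 2, "CA")), [4, 5, 6])

    def test_multi_model_keeps_first(self, tmp_path):
        text = (
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  ALA A   1       9.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "END\n"
        )
        p = tmp_path / "multi.pdb"
        p.write_text(text)
        m = read_structure(p)
        assert len(m) == 1
        assert m.position(("A", 1, "CA"))[0] == pytest.approx(1.0)
        second = read_structure(p, model_index=1)
        assert second.position(("A", 1, "CA"))[0] == pytest.approx(9.0)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.70  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        m = read_structure(p)
        assert len(m) == 1
        assert m.position(("A", 1, "CA"))[0] == pytest.approx(2.0)

    def test_residue_number_overflow_is_format_error(self, tmp_path):
        m = StructureModel([AtomRecord("A", 100000, "ALA", "CA", np.zeros(3))])
        with pytest.raises(FormatError, match="100000"):
            write_structure(m, tmp_path / "x.pdb", "pdb")

    def test_empty_write_and_missing_read(self, tmp_path):
        with pytest.raises(EmptyStructureError):
            write_structure(StructureModel([]), tmp_path / "x.pdb")
        with pytest.raises(IOError):
            read_structure(tmp_path / "absent.pdb")


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(6, 3))
        tr, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation(self, rng):
        pts = rng.normal(size=(5, 3))
        tr, rmsd = superpose(pts, pts + np.array([5.0, 0, 0]))
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(tr.translation, [5, 0, 0], atol=1e-9)

    def test_matches_independent_kabsch(self, rng):
        """Cross-check against a hand-rolled SVD solution of the same fit."""
        for _ in range(25):
            n = int(rng.integers(3, 11))
            mob = rng.normal(size=(n, 3))
            tgt = rng.normal(size=(n, 3))
            _, rmsd = superpose(mob, tgt)
            # independent oracle: Kabsch with explicit reflection correction
            mc, tc = mob.mean(0), tgt.mean(0)
            h = (mob - mc).T @ (tgt - tc)
            u, s, vt = np.linalg.svd(h)
            d = np.sign(np.linalg.det(vt.T @ u.T))
            rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
            fitted = (mob - mc) @ rot.T
            oracle = np.sqrt((((fitted) - (tgt - tc)) ** 2).sum() / n)
            assert rmsd == pytest.approx(oracle, abs=1e-9)

    def test_chiral_set_never_reflected(self, rng):
        pts = np.array([[0, 0, 0], [3, 0, 0], [0, 2, 0], [0, 0, 5.0]])
        mirror = pts * np.array([1, 1, -1.0])
        tr, rmsd = superpose(pts, mirror)
        assert rmsd > 0.5
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)
        # brute force: no proper rotation reaches rmsd 0 on a chiral set
        best = min(
            np.sqrt(
                (((pts - pts.mean(0)) @ Rotation.random(random_state=k).as_matrix().T
                   - (mirror - mirror.mean(0))) ** 2).sum() / 4
            )
            for k in range(500)
        )
        assert best > 0.1

    def test_invariant_to_rigid_pretransform(self, rng):
        mob = rng.normal(size=(8, 3))
        tgt = rng.normal(size=(8, 3))
        _, base = superpose(mob, tgt)
        for k in range(5):
            pre = RigidTransform(
                Rotation.random(random_state=k).as_matrix(), rng.normal(size=3)
            )
            _, moved = superpose(pre.apply(mob), tgt)
            assert moved == pytest.approx(base, abs=1e-9)

    def test_degenerate_inputs(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line + 1.0)
        with pytest.raises(DegenerateGeometryError):
            superpose(line[:2], line[:2])


class TestGeometry:
    def test_end_to_end_converts_to_nm(self):
        m = StructureModel(
            [
                AtomRecord("A", 1, "ALA", "CA", np.zeros(3)),
                AtomRecord("A", 2, "ALA", "CA", np.array([800.0, 0, 0])),
            ]
        )
        assert end_to_end_length(m, ("A", 1, "CA"), ("A", 2, "CA")) == pytest.approx(80.0)
        assert end_to_end_length(m, ("A", 1, "CA"), ("A", 1, "CA")) == 0.0
        with pytest.raises(SiteLookupError, match="A:9"):
            end_to_end_length(m, ("A", 9, "CA"), ("A", 1, "CA"))

    def test_clash_count_simple_and_tiny_cutoff(self):
        m = StructureModel(
            [
                AtomRecord("A", 1, "ALA", "CA", np.zeros(3)),
                AtomRecord("B", 1, "ALA", "CA", np.array([2.0, 0, 0])),
            ]
        )
        assert clash_count(m, cutoff=3.0, min_sequence_separation=2) == 1
        assert clash_count(m, cutoff=0.1, min_sequence_separation=2) == 0

    def test_ideal_helix_has_no_clashes(self):
        atoms = [
            AtomRecord("A", i, "ALA", "CA", xyz)
            for i, xyz in enumerate(ideal_helix(40), start=1)
        ]
        assert clash_count(StructureModel(atoms), 3.0, 2) == 0

    def test_clash_count_matches_naive_double_loop(self, rng):
        atoms = []
        for chain in "AB":
            for i in range(1, 40):
                atoms.append(
                    AtomRecord(chain, i, "ALA", "CA", rng.uniform(0, 20, size=3))
                )
        m = StructureModel(atoms)
        cutoff, sep = 4.0, 3
        naive = 0
        for x in range(len(atoms)):
            for y in range(x + 1, len(atoms)):
                a, b = atoms[x], atoms[y]
                if (
                    a.chain_id == b.chain_id
                    and abs(a.residue_number - b.residue_number) < sep
                ):
                    continue
                if np.linalg.norm(a.position - b.position) < cutoff:
                    naive += 1
        assert clash_count(m, cutoff, sep) == naive

    def test_dimer_rmsd_ignores_chain_relabeling(self):
        m = two_chain_model(20)
        swapped = StructureModel(
            [
                AtomRecord(
                    {"A": "B", "B": "A"}[a.chain_id],
                    a.residue_number,
                    a.residue_name,
                    a.atom_name,
                    a.position,
                )
                for a in m
            ]
        )
        assert ca_rmsd(m, swapped) > 1.0
        assert dimer_rmsd(m, swapped) == pytest.approx(0.0, abs=1e-12)
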