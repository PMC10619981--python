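"""Coordinate model, PDB/mmCIF I/O and rigid-body geometry.

The in-memory representation is deliberately small: a flat, ordered list of
atom records with a hash index on (chain, residue number, atom name).  All
coordinates are in Angstrom and residue numbers are 1-based positions in the
full-length protein sequence, so crosslink sites and fragment intervals join
directly against the model without renumbering.  File I/O is delegated to
gemmi; superposition uses the least-squares proper-rotation (Kabsch) fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    EmptyStructureError,
    FormatError,
    SiteLookupError,
)

Site = tuple[str, int, str]  # (chain_id, residue_number, atom_name)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: chain label, 1-based residue number, names, position (A)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {pos!r}")
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


class StructureModel:
    """Ordered atom collection with unique (chain, residue, atom) triples."""

    def __init__(self, atoms: Iterable[AtomRecord], metadata: dict | None = None):
        self._atoms: list[AtomRecord] = list(atoms)
        self.metadata: dict = dict(metadata or {})
        self._index: dict[Site, int] = {}
        for i, a in enumerate(self._atoms):
            key = (a.chain_id, a.residue_number, a.atom_name)
            if key in self._index:
                raise ValueError(f"duplicate atom {key}")
            self._index[key] = i
        self._coords = (
            np.array([a.position for a in self._atoms], dtype=float)
            if self._atoms
            else np.empty((0, 3))
        )

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self._atoms)

    @property
    def atoms(self) -> Sequence[AtomRecord]:
        return tuple(self._atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in file order (read-only view)."""
        v = self._coords.view()
        v.flags.writeable = False
        return v

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self._atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residue_numbers(self, chain_id: str) -> list[int]:
        seen: dict[int, None] = {}
        for a in self._atoms:
            if a.chain_id == chain_id:
                seen.setdefault(a.residue_number, None)
        return sorted(seen)

    def has_site(self, site: Site) -> bool:
        return site in self._index

    def position(self, site: Site) -> np.ndarray:
        try:
            return self._coords[self._index[site]]
        except KeyError:
            chain, res, atom = site
            available = sorted(
                {a.residue_number for a in self._atoms if a.chain_id == chain}
            )
            raise SiteLookupError(
                f"site {chain}:{res}@{atom} not in model; chain {chain!r} has "
                f"{len(available)} residues"
                + (f" spanning {available[0]}-{available[-1]}" if available else "")
            ) from None

    # -- derived models -----------------------------------------------------------
    def select(
        self,
        chain_id: str | None = None,
        residue_range: tuple[int, int] | None = None,
        atom_name: str | None = None,
    ) -> "StructureModel":
        """Subset by chain, inclusive residue interval and/or atom name."""

        def keep(a: AtomRecord) -> bool:
            if chain_id is not None and a.chain_id != chain_id:
                return False
            if residue_range is not None and not (
                residue_range[0] <= a.residue_number <= residue_range[1]
            ):
                return False
            if atom_name is not None and a.atom_name != atom_name:
                return False
            return True

        return StructureModel([a for a in self._atoms if keep(a)], self.metadata)

    def transformed(self, transform: RigidTransform) -> "StructureModel":
        new_coords = transform.apply(self._coords)
        atoms = [
            AtomRecord(a.chain_id, a.residue_number, a.residue_name, a.atom_name, xyz)
            for a, xyz in zip(self._atoms, new_coords)
        ]
        return StructureModel(atoms, self.metadata)

    @staticmethod
    def merge(models: Sequence["StructureModel"]) -> "StructureModel":
        """Concatenate models; duplicated sites keep the earliest occurrence."""
        atoms: list[AtomRecord] = []
        seen: set[Site] = set()
        for m in models:
            for a in m:
                key = (a.chain_id, a.residue_number, a.atom_name)
                if key not in seen:
                    seen.add(key)
                    atoms.append(a)
        return StructureModel(atoms)


# ---------------------------------------------------------------------------
# File I/O (gemmi)
# ---------------------------------------------------------------------------

def _from_gemmi(structure: gemmi.Structure, model_index: int) -> StructureModel:
    if len(structure) == 0:
        raise EmptyStructureError(f"no models in {structure.name!r}")
    model = structure[model_index]
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            best: dict[str, tuple[float, gemmi.Atom]] = {}
            for atom in residue:
                if atom.is_hydrogen():
                    continue
                occ = atom.occ if atom.occ is not None else 1.0
                prev = best.get(atom.name)
                if prev is None or occ > prev[0]:  # ties keep first encountered
                    best[atom.name] = (occ, atom)
            for name, (_, atom) in best.items():
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                )
    if not atoms:
        raise EmptyStructureError("structure contains zero (non-hydrogen) atoms")
    return StructureModel(atoms, metadata={"source": structure.name})


def read_structure(
    path: str | Path, format: str = "auto", model_index: int = 0
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Multi-model files yield the model at ``model_index`` (first by default).
    Hydrogens are dropped; alternate locations keep the highest occupancy.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such coordinate file: {path}")
    if format == "pdb":
        st = gemmi.read_pdb(str(path))
    elif format == "mmcif":
        doc = gemmi.cif.read(str(path))
        st = gemmi.make_structure_from_block(doc.sole_block())
    elif format == "auto":
        st = gemmi.read_structure(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    st.setup_entities()
    return _from_gemmi(st, model_index)


def _to_gemmi(model: StructureModel, name: str = "kinfold") -> gemmi.Structure:
    # group atoms by (chain, residue) preserving file order, then build the
    # gemmi hierarchy bottom-up (gemmi add_* methods copy their argument)
    by_chain: dict[str, dict[tuple[int, str], list[AtomRecord]]] = {}
    for a in model:
        by_chain.setdefault(a.chain_id, {}).setdefault(
            (a.residue_number, a.residue_name), []
        ).append(a)

    st = gemmi.Structure()
    st.name = name
    gm = gemmi.Model("1")
    for chain_id, residues in by_chain.items():
        ch = gemmi.Chain(chain_id)
        for (resnum, resname), recs in residues.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            for a in recs:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.pos = gemmi.Position(*a.position)
                atom.occ = 1.0
                atom.b_iso = 0.0
                element = a.atom_name.strip()[:1] or "C"
                try:
                    atom.element = gemmi.Element(element)
                except Exception:
                    atom.element = gemmi.Element("C")
                res.add_atom(atom)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path, format: str = "pdb") -> None:
    """Write a model as PDB (fixed-column) or mmCIF."""
    if len(model) == 0:
        raise EmptyStructureError("refusing to write an empty model")
    if format == "pdb":
        for a in model:
            if a.residue_number > 9999:
                raise FormatError(
                    f"residue_number {a.residue_number} exceeds the PDB column limit "
                    "(9999)"
                )
            if len(a.chain_id) > 1:
                raise FormatError(
                    f"chain_id {a.chain_id!r} does not fit the single-character PDB "
                    "chain column"
                )
        _to_gemmi(model).write_pdb(str(path))
    elif format == "mmcif":
        _to_gemmi(model).make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Rigid-body geometry
# ---------------------------------------------------------------------------

def superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares proper-rotation fit of ``mobile`` onto ``target``.

    Returns the transform and the post-fit RMSD (A).  Reflections are never
    returned, so a chiral point set fit against its mirror image keeps a
    positive RMSD.
    """
    mob = np.asarray(mobile, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if mob.shape != tgt.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and target must be matching (N, 3) arrays")
    n = mob.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {n}")
    mc, tc = mob.mean(axis=0), tgt.mean(axis=0)
    mob0, tgt0 = mob - mc, tgt - tc
    if np.linalg.matrix_rank(mob0, tol=1e-8) < 2:
        raise DegenerateGeometryError("mobile points are collinear")
    rot, _ = Rotation.align_vectors(tgt0, mob0)
    R = rot.as_matrix()
    t = tc - R @ mc
    diff = mob0 @ R.T - tgt0
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return RigidTransform(R, t), rmsd


def superpose_sites(
    mobile_model: StructureModel,
    target_model: StructureModel,
    mobile_sites: Sequence[Site],
    target_sites: Sequence[Site],
) -> tuple[RigidTransform, float]:
    """Superpose paired sites of two models (convenience wrapper)."""
    mob = np.array([mobile_model.position(s) for s in mobile_sites])
    tgt = np.array([target_model.position(s) for s in target_sites])
    return superpose(mob, tgt)


def end_to_end_length(model: StructureModel, site_a: Site, site_b: Site) -> float:
    """Distance between two sites, in nm (coordinates are in A)."""
    return float(np.linalg.norm(model.position(site_a) - model.position(site_b))) / 10.0


def clash_count(
    model: StructureModel, cutoff: float = 3.0, min_sequence_separation: int = 2
) -> int:
    """Count CA-CA pairs closer than ``cutoff`` A (each unordered pair once).

    Same-chain pairs with |i - j| < min_sequence_separation are excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca = [a for a in model if a.atom_name == "CA"]
    if len(ca) < 2:
        return 0
    coords = np.array([a.position for a in ca])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    count = 0
    for i, j in pairs:
        ai, aj = ca[i], ca[j]
        if (
            ai.chain_id == aj.chain_id
            and abs(ai.residue_number - aj.residue_number) < min_sequence_separation
        ):
            continue
        count += 1
    return count


def ca_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_map: Mapping[str, str] | None = None,
) -> float:
    """RMSD over shared CA sites, without re-superposition.

    ``chain_map`` renames chains of ``model_a`` before matching (e.g.
    ``{"A": "B", "B": "A"}`` to compare a homodimer up to chain relabeling).
    """
    pa, pb = [], []
    for a in model_a:
        if a.atom_name != "CA":
            continue
        chain = chain_map.get(a.chain_id, a.chain_id) if chain_map else a.chain_id
        site = (chain, a.residue_number, "CA")
        if model_b.has_site(site):
            pa.append(a.position)
            pb.append(model_b.position(site))
    if not pa:
        raise SiteLookupError("models share no CA sites")
    pa, pb = np.array(pa), np.array(pb)
    return float(np.sqrt(((pa - pb) ** 2).sum(axis=1).mean()))


def dimer_rmsd(model_a: StructureModel, model_b: StructureModel) -> float:
    """CA RMSD minimized over the two chain pairings of an A/B homodimer.

    The chains of a homodimer are interchangeable copies of one sequence, so
    a model that differs from the reference only by swapping the labels A and
    B describes the same molecule.
    """
    direct = ca_rmsd(model_a, model_b)
    try:
        swapped = ca_rmsd(model_a, model_b, chain_map={"A": "B", "B": "A"})
    except SiteLookupError:
        return direct
    return min(direct, swapped)
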