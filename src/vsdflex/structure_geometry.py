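"""Charge-transfer-center electrostatics from coordinate files.

Salt bridges between the S4 basic residues and the acidic residues of
the NxxD motif (and the S2 counter-charges) are called from donor
nitrogen / acceptor carboxyl-oxygen distances with an inclusive 4.0 Å
cutoff.  PDB and mmCIF input is parsed with gemmi; only the first
model is used, one conformer per atom is retained and hydrogens are
ignored.

Donor atoms: Lys NZ; Arg NE, NH1, NH2 (the three guanidinium
nitrogens — some sources list them as Nζ/Nη1/Nη2, an alias of the
same atoms).  Acceptor atoms: the two carboxyl oxygens of Asp
(OD1/OD2) or Glu (OE1/OE2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

SALT_BRIDGE_CUTOFF: float = 4.0

DONOR_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}
ACCEPTOR_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


class StructureFormatError(ValueError):
    """Unparseable or empty coordinate file."""


class SelectionError(ValueError):
    """A residue selector resolved to zero or several residues."""


@dataclass(frozen=True)
class Atom:
    chain: str
    res_name: str
    res_seq: int
    atom_name: str
    element: str
    pos: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos)


@dataclass(frozen=True)
class StructureModel:
    """Flat heavy-atom list of one model (single conformer per atom)."""

    atoms: tuple[Atom, ...]
    model_id: str = "1"

    def residue_atoms(
        self, chain: str | None, res_seq: int, res_name: str | None = None
    ) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.res_seq == res_seq
            and (chain is None or a.chain == chain)
            and (res_name is None or a.res_name == res_name.upper())
        ]


@dataclass(frozen=True)
class SaltBridgeRecord:
    donor_chain: str
    donor_res_name: str
    donor_res_seq: int
    donor_atom: str
    acceptor_chain: str
    acceptor_res_name: str
    acceptor_res_seq: int
    acceptor_atom: str
    distance: float
    is_bridge: bool


#: Residue selector: (chain or None, residue number, residue name or None).
Selector = tuple[str | None, int, str | None]


def read_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read the first model of a PDB or mmCIF file.

    Hydrogens are dropped; where alternate locations exist the highest
    occupancy conformer is kept (ties: alphabetically first altloc).
    """
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unsupported structure format: {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models")
    model = st[0]
    best: dict[tuple[str, int, str], Atom] = {}
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                rec = Atom(
                    chain=chain.name,
                    res_name=residue.name.upper(),
                    res_seq=residue.seqid.num,
                    atom_name=atom.name,
                    element=atom.element.name,
                    pos=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=atom.occ,
                    altloc=atom.altloc or "",
                )
                key = (rec.chain, rec.res_seq, rec.atom_name)
                held = best.get(key)
                if (
                    held is None
                    or rec.occupancy > held.occupancy + 1e-12
                    or (
                        abs(rec.occupancy - held.occupancy) <= 1e-12
                        and rec.altloc < held.altloc
                    )
                ):
                    best[key] = rec
    atoms = tuple(best.values())
    if not atoms:
        raise StructureFormatError(f"{path}: model contains no heavy atoms")
    for atom in atoms:
        if not all(math.isfinite(v) for v in atom.pos):
            raise StructureFormatError(f"{path}: non-finite coordinates")
    return StructureModel(atoms=atoms, model_id=str(model.num))


def donor_acceptor_atoms(res_name: str) -> tuple[str, ...]:
    """Donor nitrogen / acceptor oxygen atom names for a residue type."""
    res = res_name.upper()
    if res in DONOR_ATOMS:
        return DONOR_ATOMS[res]
    if res in ACCEPTOR_ATOMS:
        return ACCEPTOR_ATOMS[res]
    raise ValueError(
        f"residue {res_name!r} is not a salt-bridge donor (LYS/ARG) "
        f"or acceptor (ASP/GLU)"
    )


def _resolve(model: StructureModel, sel: Selector) -> list[Atom]:
    chain, res_seq, res_name = sel
    atoms = model.residue_atoms(chain, res_seq, res_name)
    chains = sorted({a.chain for a in atoms})
    if not atoms:
        raise SelectionError(f"selector {sel!r} matches no residue")
    if len(chains) > 1:
        if chain is None:
            logger.warning(
                "selector %r ambiguous across chains %s; using chain %s",
                sel, chains, chains[0],
            )
            atoms = [a for a in atoms if a.chain == chains[0]]
        else:
            raise SelectionError(f"selector {sel!r} matches several residues")
    names = {(a.chain, a.res_name) for a in atoms}
    if len(names) > 1:
        raise SelectionError(f"selector {sel!r} matches several residues: {names}")
    return atoms


def min_pair_distance(
    model: StructureModel,
    res_a: Selector,
    res_b: Selector,
    atom_filter: tuple[Sequence[str] | None, Sequence[str] | None] | None = None,
) -> float:
    """Minimum distance (Å) between two residues' atom sets.

    By default the donor/acceptor sets are used when the residue type
    has them, otherwise all heavy atoms.  ``atom_filter`` overrides the
    per-residue atom-name lists.
    """
    atoms_a = _resolve(model, res_a)
    atoms_b = _resolve(model, res_b)

    def pick(atoms: list[Atom], names: Sequence[str] | None) -> list[Atom]:
        if names is None:
            res = atoms[0].res_name
            if res in DONOR_ATOMS or res in ACCEPTOR_ATOMS:
                names = donor_acceptor_atoms(res)
            else:
                return atoms
        chosen = [a for a in atoms if a.atom_name in names]
        return chosen or atoms

    filt_a, filt_b = atom_filter if atom_filter is not None else (None, None)
    set_a, set_b = pick(atoms_a, filt_a), pick(atoms_b, filt_b)
    return min(
        float(np.linalg.norm(a.xyz - b.xyz)) for a in set_a for b in set_b
    )


def detect_salt_bridges(
    model: StructureModel,
    donors: Iterable[Selector],
    acceptors: Iterable[Selector],
    cutoff: float = SALT_BRIDGE_CUTOFF,
    reporting_range: float = math.inf,
) -> list[SaltBridgeRecord]:
    """One record per donor-atom/acceptor-atom pair within range.

    ``is_bridge`` is true for distances <= ``cutoff`` (inclusive, as
    the criterion is stated).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    records: list[SaltBridgeRecord] = []
    for donor_sel in donors:
        donor_atoms_all = _resolve(model, donor_sel)
        donor_res = donor_atoms_all[0].res_name
        if donor_res not in DONOR_ATOMS:
            raise ValueError(f"{donor_res} is not a donor residue (LYS/ARG)")
        d_atoms = [a for a in donor_atoms_all if a.atom_name in DONOR_ATOMS[donor_res]]
        for acceptor_sel in acceptors:
            acc_atoms_all = _resolve(model, acceptor_sel)
            acc_res = acc_atoms_all[0].res_name
            if acc_res not in ACCEPTOR_ATOMS:
                raise ValueError(f"{acc_res} is not an acceptor residue (ASP/GLU)")
            a_atoms = [
                a for a in acc_atoms_all if a.atom_name in ACCEPTOR_ATOMS[acc_res]
            ]
            for da in d_atoms:
                for aa in a_atoms:
                    dist = float(np.linalg.norm(da.xyz - aa.xyz))
                    if dist <= reporting_range:
                        records.append(
                            SaltBridgeRecord(
                                donor_chain=da.chain,
                                donor_res_name=da.res_name,
                                donor_res_seq=da.res_seq,
                                donor_atom=da.atom_name,
                                acceptor_chain=aa.chain,
                                acceptor_res_name=aa.res_name,
                                acceptor_res_seq=aa.res_seq,
                                acceptor_atom=aa.atom_name,
                                distance=dist,
                                is_bridge=dist <= cutoff,
                            )
                        )
    return records


def superpose_motif(
    model_a: StructureModel,
    model_b: StructureModel,
    correspondence: Sequence[tuple[Selector, Selector]],
) -> float:
    """Least-squares Cα superposition RMSD (Å) over corresponding residues.

    Kabsch algorithm: optimal rigid-body rotation after centroid
    removal, with the determinant correction against improper
    rotations.  Needs at least 3 residue pairs with Cα atoms.
    """
    if len(correspondence) < 3:
        raise ValueError("need at least 3 corresponding residue pairs")

    def ca(model: StructureModel, sel: Selector) -> np.ndarray:
        atoms = [a for a in _resolve(model, sel) if a.atom_name == "CA"]
        if not atoms:
            raise SelectionError(f"no Cα atom for selector {sel!r}")
        return atoms[0].xyz

    pts_a = np.array([ca(model_a, sa) for sa, _ in correspondence])
    pts_b = np.array([ca(model_b, sb) for _, sb in correspondence])
    a_cent = pts_a - pts_a.mean(axis=0)
    b_cent = pts_b - pts_b.mean(axis=0)
    u, _, vt = np.linalg.svd(a_cent.T @ b_cent)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    moved = a_cent @ rot
    return float(np.sqrt(np.mean(np.sum((moved - b_cent) ** 2, axis=1))))


def write_salt_bridge_tsv(
    records: Iterable[SaltBridgeRecord], path: str | Path
) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            [
                "donor_chain", "donor_res", "donor_atom",
                "acceptor_chain", "acceptor_res", "acceptor_atom",
                "distance_A", "is_bridge",
            ]
        )
        for r in records:
            writer.writerow(
                [
                    r.donor_chain, f"{r.donor_res_name}{r.donor_res_seq}", r.donor_atom,
                    r.acceptor_chain, f"{r.acceptor_res_name}{r.acceptor_res_seq}",
                    r.acceptor_atom, f"{r.distance:.3f}", str(r.is_bridge).lower(),
                ]
            )
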