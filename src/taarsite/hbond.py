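"""Geometric hydrogen-bond detection between a receptor and its ligand.

Ligand binding in a docked pose is read off as the presence of hydrogen
bonds, using an explicit geometric criterion: donor–acceptor heavy-atom
distance at most ``max_da_distance`` (default 3.5 Angstrom, the standard
distance criterion), with a D-H...A angle test applied only when the
pose actually contains hydrogens — docking output usually does not.
Amine–carboxylate salt bridges count as hydrogen bonds.  Only
receptor<->ligand bonds are reported; intra-molecular pairs are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, ComplexPose

__all__ = [
    "HBondCriteria",
    "ChemTyping",
    "HBondContact",
    "load_default_typing",
    "type_atoms",
    "detect_hbonds",
    "residue_bond_set",
]

#: Maximum covalent X-H bond length used to associate hydrogens with donors.
_MAX_DH_COVALENT = 1.3


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion.

    Parameters
    ----------
    max_da_distance : float
        Donor–acceptor heavy-atom cutoff in Angstrom.
    min_dha_angle : float
        Minimum D-H...A angle in degrees, applied only when
        ``use_hydrogens`` is set and a hydrogen is covalently bound
        to the donor.
    use_hydrogens : bool
        Whether to apply the angular test at all.
    """

    max_da_distance: float = 3.5
    min_dha_angle: float = 120.0
    use_hydrogens: bool = False

    def __post_init__(self) -> None:
        if not 2.0 <= self.max_da_distance <= 5.0:
            raise ValueError("max_da_distance must be within [2.0, 5.0] A")
        if not 90.0 <= self.min_dha_angle <= 180.0:
            raise ValueError("min_dha_angle must be within [90, 180] degrees")


@dataclass(frozen=True)
class ChemTyping:
    """Donor/acceptor lookup tables keyed by (residue_name, atom_name).

    ``"*"`` as residue name matches protein backbone atoms of any
    residue.  Ligand residue names must be explicitly typed; an unknown
    ligand raises at typing time.
    """

    donor_atoms: dict[str, frozenset[str]]
    acceptor_atoms: dict[str, frozenset[str]]
    ligand_resnames: frozenset[str]

    def is_donor(self, residue_name: str, atom_name: str) -> bool:
        return atom_name in self.donor_atoms.get(residue_name, frozenset()) or (
            residue_name not in self.ligand_resnames
            and atom_name in self.donor_atoms.get("*", frozenset())
        )

    def is_acceptor(self, residue_name: str, atom_name: str) -> bool:
        return atom_name in self.acceptor_atoms.get(residue_name, frozenset()) or (
            residue_name not in self.ligand_resnames
            and atom_name in self.acceptor_atoms.get("*", frozenset())
        )

    @classmethod
    def from_table(cls, text: str) -> "ChemTyping":
        donors: dict[str, set[str]] = {}
        acceptors: dict[str, set[str]] = {}
        ligands: set[str] = set()
        header_seen = False
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # first non-comment line is the header
                continue
            resname, atom_name, kind, role = line.split("\t")
            if kind == "ligand":
                ligands.add(resname)
            if role in ("donor", "both"):
                donors.setdefault(resname, set()).add(atom_name)
            if role in ("acceptor", "both"):
                acceptors.setdefault(resname, set()).add(atom_name)
        return cls(
            donor_atoms={k: frozenset(v) for k, v in donors.items()},
            acceptor_atoms={k: frozenset(v) for k, v in acceptors.items()},
            ligand_resnames=frozenset(ligands),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ChemTyping":
        return cls.from_table(Path(path).read_text())


def load_default_typing() -> ChemTyping:
    """Typing for the five biogenic-amine ligands and protein polar groups."""
    text = resources.files("taarsite.data").joinpath("chem_typing.tsv").read_text()
    return ChemTyping.from_table(text)


@dataclass(frozen=True)
class HBondContact:
    """One receptor<->ligand hydrogen bond (exactly one side is ligand)."""

    donor: AtomRecord
    acceptor: AtomRecord
    distance: float
    angle: float | None
    receptor_residue: tuple[str, int, str]


def type_atoms(
    pose: ComplexPose, typing: ChemTyping
) -> tuple[list[AtomRecord], list[AtomRecord]]:
    """Split pose atoms into hydrogen-bond donors and acceptors.

    Carbon atoms are never polar; an untyped ligand residue name or a
    ligand with no polar atoms is an error (its chemistry is unknown to
    the analysis).
    """
    for a in pose.ligand_atoms:
        if a.residue_name not in typing.ligand_resnames:
            raise ValueError(
                f"unknown ligand chemistry: residue {a.residue_name!r} "
                "is not in the typing table"
            )
    donors: list[AtomRecord] = []
    acceptors: list[AtomRecord] = []
    any_ligand_polar = False
    for a in pose.atoms:
        if a.element in ("C", "H"):
            continue
        d = typing.is_donor(a.residue_name, a.atom_name)
        acc = typing.is_acceptor(a.residue_name, a.atom_name)
        if (d or acc) and a.residue_name in typing.ligand_resnames:
            any_ligand_polar = True
        if d:
            donors.append(a)
        if acc:
            acceptors.append(a)
    if not any_ligand_polar:
        raise ValueError(
            "unknown ligand chemistry: ligand has no typed donor/acceptor atoms"
        )
    return donors, acceptors


def _hydrogens_on(pose: ComplexPose, donor: AtomRecord) -> list[AtomRecord]:
    pool = pose.ligand_atoms if donor.is_hetero else pose.receptor_atoms
    out = []
    dxyz = np.asarray(donor.coords)
    for a in pool:
        if a.element != "H":
            continue
        if (
            a.chain_id == donor.chain_id
            and a.residue_number == donor.residue_number
            and float(np.linalg.norm(np.asarray(a.coords) - dxyz)) <= _MAX_DH_COVALENT
        ):
            out.append(a)
    return out


def _angle_ok(
    pose: ComplexPose,
    donor: AtomRecord,
    acceptor: AtomRecord,
    criteria: HBondCriteria,
) -> tuple[bool, float | None]:
    """Apply the D-H...A test when hydrogens are available, else pass."""
    if not criteria.use_hydrogens:
        return True, None
    hydrogens = _hydrogens_on(pose, donor)
    if not hydrogens:
        return True, None
    d = np.asarray(donor.coords)
    a = np.asarray(acceptor.coords)
    best: float | None = None
    for h in hydrogens:
        hx = np.asarray(h.coords)
        v1 = d - hx
        v2 = a - hx
        cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if best is None or ang > best:
            best = ang
    return best >= criteria.min_dha_angle, best


def detect_hbonds(
    pose: ComplexPose,
    criteria: HBondCriteria | None = None,
    typing: ChemTyping | None = None,
) -> list[HBondContact]:
    """All receptor<->ligand hydrogen bonds in a pose.

    A contact is reported for every (donor, acceptor) pair with exactly
    one ligand member whose heavy-atom distance is within the cutoff
    (and, when hydrogens are present and requested, whose D-H...A angle
    passes).  The list is sorted by (receptor residue number, distance).

    The neighbour search uses a KD-tree; the contract is defined by the
    equivalent all-pairs predicate.
    """
    criteria = criteria or HBondCriteria()
    typing = typing or load_default_typing()
    donors, acceptors = type_atoms(pose, typing)
    if not donors or not acceptors:
        return []
    ligand_ids = {id(a) for a in pose.ligand_atoms}
    d_xyz = np.array([a.coords for a in donors])
    a_xyz = np.array([a.coords for a in acceptors])
    tree_d = cKDTree(d_xyz)
    tree_a = cKDTree(a_xyz)
    contacts: list[HBondContact] = []
    for i, js in enumerate(tree_d.query_ball_tree(tree_a, r=criteria.max_da_distance)):
        don = donors[i]
        for j in js:
            acc = acceptors[j]
            don_is_lig = id(don) in ligand_ids
            acc_is_lig = id(acc) in ligand_ids
            if don_is_lig == acc_is_lig:
                continue  # intra-receptor or intra-ligand
            dist = float(np.linalg.norm(d_xyz[i] - a_xyz[j]))
            ok, ang = _angle_ok(pose, don, acc, criteria)
            if not ok:
                continue
            rec = acc if don_is_lig else don
            contacts.append(
                HBondContact(
                    donor=don,
                    acceptor=acc,
                    distance=dist,
                    angle=ang,
                    receptor_residue=(rec.chain_id, rec.residue_number, rec.residue_name),
                )
            )
    contacts.sort(key=lambda c: (c.receptor_residue[1], c.distance))
    return contacts


def residue_bond_set(
    pose: ComplexPose,
    criteria: HBondCriteria | None = None,
    typing: ChemTyping | None = None,
) -> set[tuple[str, int]]:
    """Receptor residues forming at least one hydrogen bond to the ligand."""
    return {
        (c.receptor_residue[0], c.receptor_residue[1])
        for c in detect_hbonds(pose, criteria, typing)
    }
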