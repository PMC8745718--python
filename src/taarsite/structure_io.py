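"""Read, write and query receptor–ligand complexes in PDB format.

A complex is one docked pose: the receptor as ``ATOM`` records and the
ligand as ``HETATM`` records (some docking programs emit ligands as
``ATOM``, so ligand routing is by residue-name allowlist, not record
type).  Files are single-model, single-conformer docking output; altLoc
codes other than blank or 'A' are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

__all__ = [
    "AtomRecord",
    "ComplexPose",
    "PDBParseError",
    "PDBFormatError",
    "DEFAULT_LIGAND_RESNAMES",
    "read_complex",
    "read_complex_file",
    "write_complex",
    "select_residue",
]

#: Residue names recognised as ligands by default: beta-phenylethylamine,
#: tyramine, putrescine, cadaverine and gamma-aminobutyric acid.
DEFAULT_LIGAND_RESNAMES = frozenset({"PEA", "TYM", "PUT", "CAD", "ABU"})


class PDBParseError(ValueError):
    """A PDB line could not be parsed; the message names the line number."""


class PDBFormatError(ValueError):
    """A pose cannot be serialised within PDB v3.3 fixed columns."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a receptor or ligand.

    Coordinates are in Angstrom. ``residue_number`` is the author
    numbering taken verbatim from the file (1-based), so receptor
    residues can be addressed the way the literature does (Asp68,
    Asp102, ...).
    """

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: tuple[float, float, float]
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates: {self.coords}")


@dataclass
class ComplexPose:
    """One receptor + ligand structure (a single docked pose)."""

    receptor_atoms: list[AtomRecord]
    ligand_atoms: list[AtomRecord]
    pose_id: str = ""
    condition: object | None = None  # ConditionKey once assigned by the pipeline

    def __post_init__(self) -> None:
        if not self.ligand_atoms:
            raise ValueError("no ligand: ligand_atoms is empty")
        if not self.receptor_atoms:
            raise ValueError("receptor_atoms is empty")
        if not all(a.is_hetero for a in self.ligand_atoms):
            raise ValueError("all ligand atoms must be flagged hetero")
        seen: set[tuple[str, int, str]] = set()
        for a in self.receptor_atoms:
            key = (a.chain_id, a.residue_number, a.atom_name)
            if key in seen:
                raise ValueError(f"duplicate receptor atom {key}")
            seen.add(key)

    @property
    def atoms(self) -> list[AtomRecord]:
        return self.receptor_atoms + self.ligand_atoms


def _infer_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: malformed {what} field {text.strip()!r}"
        ) from None


def read_complex(
    pdb_text: str,
    ligand_resnames: Iterable[str] = DEFAULT_LIGAND_RESNAMES,
) -> ComplexPose:
    """Parse PDB text into a :class:`ComplexPose`.

    Every ``ATOM``/``HETATM`` line becomes exactly one :class:`AtomRecord`
    (altLoc other than blank/'A' excepted).  Records whose residue name is
    in ``ligand_resnames`` become ligand atoms regardless of record type.

    Raises
    ------
    PDBParseError
        On a malformed coordinate/serial/residue-number field, naming the
        offending line number.
    ValueError
        If no ligand atoms are found ("no ligand").
    """
    ligand_set = {r.upper() for r in ligand_resnames}
    receptor: list[AtomRecord] = []
    ligand: list[AtomRecord] = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        line = line.ljust(80)
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue  # docking output is single-conformer
        atom_name = line[12:16].strip()
        resname = line[17:20].strip().upper()
        chain_id = line[21]
        resnum_txt = line[22:26].strip()
        try:
            resnum = int(resnum_txt)
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: malformed residue number {resnum_txt!r}"
            ) from None
        x = _parse_float(line[30:38], "x coordinate", lineno)
        y = _parse_float(line[38:46], "y coordinate", lineno)
        z = _parse_float(line[46:54], "z coordinate", lineno)
        element = line[76:78].strip() or _infer_element(atom_name)
        serial_txt = line[6:11].strip()
        try:
            serial = int(serial_txt)
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: malformed serial {serial_txt!r}"
            ) from None
        # Allowlist decides ligand membership; non-allowlisted HETATM
        # (waters, ions) stay with the receptor environment.
        is_ligand = resname in ligand_set
        try:
            record = AtomRecord(
                serial=serial,
                atom_name=atom_name,
                element=element,
                residue_name=resname,
                residue_number=resnum,
                chain_id=chain_id,
                coords=(x, y, z),
                is_hetero=is_ligand or rec == "HETATM",
            )
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: {exc}") from None
        if is_ligand:
            ligand.append(replace(record, is_hetero=True))
        else:
            receptor.append(record)
    if not ligand:
        raise ValueError(
            "no ligand: no atom matched ligand residue names "
            f"{sorted(ligand_set)}"
        )
    if not receptor:
        raise ValueError("no receptor ATOM records found")
    return ComplexPose(receptor_atoms=receptor, ligand_atoms=ligand)


def read_complex_file(
    path: str | Path,
    ligand_resnames: Iterable[str] = DEFAULT_LIGAND_RESNAMES,
) -> ComplexPose:
    pose = read_complex(Path(path).read_text(), ligand_resnames)
    pose.pose_id = Path(path).stem
    return pose


def _format_atom_line(a: AtomRecord, serial: int) -> str:
    if len(a.atom_name) > 4:
        raise PDBFormatError(f"atom_name {a.atom_name!r} exceeds 4 characters")
    if len(a.residue_name) > 3:
        raise PDBFormatError(f"residue_name {a.residue_name!r} exceeds 3 characters")
    if a.residue_number > 9999:
        raise PDBFormatError(f"residue_number {a.residue_number} exceeds 9999")
    record = "HETATM" if a.is_hetero else "ATOM  "
    # Element-aligned atom-name column per PDB v3.3: one- or two-letter
    # element names start in column 14 unless the name is 4 chars long.
    name = a.atom_name
    if len(name) < 4 and len(a.element) < 2:
        name = " " + name
    x, y, z = a.coords
    return (
        f"{record}{serial:>5} {name:<4} {a.residue_name:>3} {a.chain_id}"
        f"{a.residue_number:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element:>2}"
    )


def write_complex(pose: ComplexPose) -> str:
    """Serialise a pose as PDB v3.3 text.

    Atoms are written receptor-first then ligand, renumbered serially;
    ligand atoms are ``HETATM`` records.  Coordinates keep 3 decimals
    (the PDB precision).
    """
    lines: list[str] = []
    serial = 0
    for a in pose.receptor_atoms:
        serial += 1
        lines.append(_format_atom_line(a, serial))
    lines.append("TER")
    for a in pose.ligand_atoms:
        serial += 1
        lines.append(_format_atom_line(a, serial))
    lines.append("END")
    return "\n".join(lines) + "\n"


def select_residue(
    pose: ComplexPose, chain_id: str, residue_number: int
) -> list[AtomRecord]:
    """All receptor atoms of one residue; empty list if absent."""
    return [
        a
        for a in pose.receptor_atoms
        if a.chain_id == chain_id and a.residue_number == residue_number
    ]
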