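"""Shared fixtures: tiny poses, random pose generation, brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from taarsite.hbond import ChemTyping, HBondCriteria, load_default_typing
from taarsite.structure_io import AtomRecord, ComplexPose
from taarsite.synthetic import LIGAND_TEMPLATES, load_study_config


@pytest.fixture(scope="session")
def study_config():
    return load_study_config()


@pytest.fixture(scope="session")
def typing() -> ChemTyping:
    return load_default_typing()


def make_atom(
    name: str,
    xyz,
    resname: str = "ALA",
    resnum: int = 1,
    chain: str = "A",
    serial: int = 1,
    hetero: bool = False,
    element: str | None = None,
) -> AtomRecord:
    return AtomRecord(
        serial=serial,
        atom_name=name,
        element=element or name[0],
        residue_name=resname,
        residue_number=resnum,
        chain_id=chain,
        coords=tuple(float(c) for c in xyz),
        is_hetero=hetero,
    )


def make_pose(receptor_atoms, ligand_atoms) -> ComplexPose:
    return ComplexPose(receptor_atoms=list(receptor_atoms), ligand_atoms=list(ligand_atoms))


def asp_with_ligand_n(distance: float, ligand: str = "PUT") -> ComplexPose:
    """Minimal pose: one Asp carboxylate with a ligand amine at `distance` A."""
    receptor = [
        make_atom("CA", (0, 0, 0), "ASP", 10, serial=1),
        make_atom("CG", (1.5, 0, 0), "ASP", 10, serial=2),
        make_atom("OD1", (2.5, 0, 0), "ASP", 10, serial=3),
        make_atom("OD2", (2.5, 1.5, 0), "ASP", 10, serial=4),
    ]
    template = LIGAND_TEMPLATES[ligand]
    ligand_atoms = []
    for i, (name, elem) in enumerate(template):
        # first atom at the probe distance from OD1, rest strung away
        x = 2.5 + distance + 1.5 * i
        ligand_atoms.append(
            make_atom(name, (x, 0, 0), ligand, 900, chain="L",
                      serial=100 + i, hetero=True, element=elem)
        )
    return make_pose(receptor, ligand_atoms)


_RECEPTOR_RESIDUES = [
    ("ASP", ["CA", "CB", "CG", "OD1", "OD2"]),
    ("SER", ["CA", "CB", "OG"]),
    ("ASN", ["CA", "CB", "ND2", "OD1"]),
    ("ALA", ["CA", "CB", "N", "O"]),
    ("GLY", ["CA"]),
    ("TRP", ["CA", "NE1"]),
]


def random_pose(rng: np.random.Generator, box: float = 12.0) -> ComplexPose:
    """A random small complex for oracle-equivalence testing."""
    receptor = []
    serial = 0
    n_res = rng.integers(2, 6)
    for i in range(n_res):
        resname, atom_names = _RECEPTOR_RESIDUES[rng.integers(len(_RECEPTOR_RESIDUES))]
        for name in atom_names:
            serial += 1
            receptor.append(
                make_atom(
                    name,
                    rng.uniform(0, box, 3),
                    resname,
                    resnum=10 + int(i),
                    serial=serial,
                )
            )
    ligand_name = ["PEA", "TYM", "PUT", "CAD", "ABU"][rng.integers(5)]
    ligand = []
    for j, (name, elem) in enumerate(LIGAND_TEMPLATES[ligand_name]):
        serial += 1
        ligand.append(
            make_atom(name, rng.uniform(0, box, 3), ligand_name, 900,
                      chain="L", serial=serial, hetero=True, element=elem)
        )
    return make_pose(receptor, ligand)


def oracle_hbonds(
    pose: ComplexPose, criteria: HBondCriteria, typing: ChemTyping
) -> set[tuple[int, int]]:
    """Independent all-pairs hydrogen-bond predicate.

    Returns (donor serial, acceptor serial) pairs; plain double loop with
    explicit distance math, no spatial index.
    """
    ligand_serials = {a.serial for a in pose.ligand_atoms}

    def dist(a, b):
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(a.coords, b.coords)))

    out = set()
    for don in pose.atoms:
        if don.element in ("C", "H"):
            continue
        if not typing.is_donor(don.residue_name, don.atom_name):
            continue
        for acc in pose.atoms:
            if acc.element in ("C", "H"):
                continue
            if not typing.is_acceptor(acc.residue_name, acc.atom_name):
                continue
            if (don.serial in ligand_serials) == (acc.serial in ligand_serials):
                continue
            if dist(don, acc) <= criteria.max_da_distance:
                out.add((don.serial, acc.serial))
    return out
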