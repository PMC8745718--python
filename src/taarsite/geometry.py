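"""Rigid superposition (Kabsch) RMSD and Ballesteros–Weinstein numbering.

Receptor models of one sequence are compared by the least-squares
C-alpha RMSD after optimal rigid-body superposition.  Residues are
addressed across receptors by the class-A GPCR generic numbering
``h.pp``: helix number plus position relative to the most conserved
residue of that helix, which is defined as position 50 (the ``x.50``
anchor).  Helix ranges and anchors are configuration inputs per
receptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure_io import ComplexPose

__all__ = [
    "GenericNumber",
    "BWMap",
    "RmsdMatrix",
    "kabsch_superpose",
    "rmsd_matrix",
    "bw_lookup",
    "bw_inverse",
]


@dataclass(frozen=True, order=True)
class GenericNumber:
    """Generic residue number ``helix.position`` (e.g. 3.32)."""

    helix: int
    position: int

    def __post_init__(self) -> None:
        if not 1 <= self.helix <= 7:
            raise ValueError("helix must be 1..7")
        if self.position <= 0:
            raise ValueError("position must be positive")

    def __str__(self) -> str:
        return f"{self.helix}.{self.position}"

    @classmethod
    def parse(cls, text: str) -> "GenericNumber":
        helix, position = text.split(".")
        return cls(int(helix), int(position))


@dataclass(frozen=True)
class BWMap:
    """Seven TM helix ranges plus their x.50 anchor residues.

    ``helix_ranges[i]`` is the inclusive (start, end) author-numbering
    span of helix i+1 and ``anchors[i]`` its x.50 residue.  Ranges must
    be ascending and non-overlapping, each anchor inside its range.
    """

    helix_ranges: tuple[tuple[int, int], ...]
    anchors: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.helix_ranges) != 7 or len(self.anchors) != 7:
            raise ValueError("exactly 7 helix ranges and 7 anchors required")
        prev_end = -1
        for (start, end), anchor in zip(self.helix_ranges, self.anchors):
            if start > end:
                raise ValueError(f"range ({start}, {end}) is inverted")
            if start <= prev_end:
                raise ValueError("helix ranges must be ascending, non-overlapping")
            if not start <= anchor <= end:
                raise ValueError(f"anchor {anchor} outside range ({start}, {end})")
            prev_end = end

    @classmethod
    def from_config(cls, helices: Sequence[dict]) -> "BWMap":
        """Build from config entries ``{id, start, end, anchor}``."""
        ordered = sorted(helices, key=lambda h: int(h["id"]))
        return cls(
            helix_ranges=tuple((int(h["start"]), int(h["end"])) for h in ordered),
            anchors=tuple(int(h["anchor"]) for h in ordered),
        )

    def tm_residues(self) -> list[int]:
        return [r for s, e in self.helix_ranges for r in range(s, e + 1)]


@dataclass(frozen=True)
class RmsdMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal, Angstrom

    def to_tsv(self) -> str:
        lines = ["\t".join(("model",) + self.labels)]
        for lab, row in zip(self.labels, self.values):
            lines.append("\t".join([lab] + [f"{v:.3f}" for v in row]))
        return "\n".join(lines) + "\n"


def kabsch_superpose(
    A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of B onto A.

    Returns ``(rotation, translation, rmsd)`` with
    ``A ~= B @ rotation.T + translation`` minimising the RMSD over all
    proper rigid motions (reflections excluded).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 3:
        raise ValueError("need N x 3 coordinates with N >= 3")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    P, Q = A - ca, B - cb
    U, _S, Vt = np.linalg.svd(Q.T @ P)
    # reflection case: flip the smallest singular direction to keep det=+1
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ca - R @ cb
    diff = P - Q @ R.T
    rmsd = float(np.sqrt((diff * diff).sum() / A.shape[0]))
    return R, t, rmsd


def rmsd_matrix(
    models: Sequence[ComplexPose | Sequence], atom_name: str = "CA"
) -> RmsdMatrix:
    """Pairwise C-alpha RMSD between receptor models.

    Models are matched on the intersection of (chain, residue number);
    the models share one sequence so no alignment is attempted.  Raw
    coordinate arrays (N x 3, already matched) are also accepted.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    coords: list[dict[tuple[str, int], np.ndarray]] = []
    labels: list[str] = []
    for i, m in enumerate(models):
        if isinstance(m, ComplexPose):
            sel = {
                (a.chain_id, a.residue_number): np.asarray(a.coords)
                for a in m.receptor_atoms
                if a.atom_name == atom_name
            }
            labels.append(m.pose_id or f"model_{i + 1}")
        else:
            arr = np.asarray(m, dtype=float)
            sel = {("", k): arr[k] for k in range(arr.shape[0])}
            labels.append(f"model_{i + 1}")
        coords.append(sel)
    common = set(coords[0])
    for sel in coords[1:]:
        common &= set(sel)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common residues; need >= 3")
    order = sorted(common)
    stacks = [np.array([sel[k] for k in order]) for sel in coords]
    n = len(models)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch_superpose(stacks[i], stacks[j])
            values[i, j] = values[j, i] = r
    return RmsdMatrix(labels=tuple(labels), values=values)


def bw_lookup(bw: BWMap, residue_number: int) -> GenericNumber:
    """Generic number of a TM residue; loop residues are an error."""
    for i, ((start, end), anchor) in enumerate(zip(bw.helix_ranges, bw.anchors)):
        if start <= residue_number <= end:
            return GenericNumber(helix=i + 1, position=50 + residue_number - anchor)
    raise ValueError(f"residue {residue_number} is not in a TM helix")


def bw_inverse(bw: BWMap, g: GenericNumber | str) -> int:
    """Author residue number for a generic number (inverse of lookup)."""
    if isinstance(g, str):
        g = GenericNumber.parse(g)
    start, end = bw.helix_ranges[g.helix - 1]
    residue = bw.anchors[g.helix - 1] + (g.position - 50)
    if not start <= residue <= end:
        raise ValueError(f"{g} maps to residue {residue}, outside helix {g.helix}")
    return residue
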