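"""Synthetic docking-study generator with known ground truth.

The study emulated here is a full-factorial docking design: for each
receptor, 5 structural models x 5 ligands x 5 binding-pocket options
(one Asp triplet, three Asp pairs, one unconstrained control) x 3
replicate runs x 10 poses — 3750 poses per receptor, 7500 in total.

Because no real receptor models or docked poses were deposited, poses
are generated against an idealised 7-helix scaffold: C-alpha traces of
ideal helices (1.5 A rise, 100 deg turn) on a ring, with carboxylate
pseudo-sidechains planted on the designated aspartates pointing into the
central pore.  Which Asp residues the ligand contacts in a pose is drawn
from a joint Bernoulli contact model (marginals + pairwise joints,
Frechet-feasible); ligand atoms are then placed so that hydrogen-bond
detection recovers exactly the drawn contact state: donor nitrogens
strictly inside the distance cutoff for planted contacts, every ligand
atom at least 1 A beyond the cutoff from non-contacted target residues.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

from .geometry import BWMap, bw_inverse
from .hbond import HBondCriteria
from .occupancy import ConditionKey, PocketSpec
from .structure_io import AtomRecord, ComplexPose, write_complex

__all__ = [
    "ContactModel",
    "ScaffoldSpec",
    "ReceptorConfig",
    "StudyConfig",
    "load_study_config",
    "build_scaffold",
    "sample_contact_states",
    "realize_pose",
    "build_contact_model",
    "iter_study_poses",
    "generate_study",
]

#: Rigid atom templates per ligand: (atom_name, element) in chain order.
#: Bridging (donor-capable) atoms sit at the chain ends.
LIGAND_TEMPLATES: dict[str, list[tuple[str, str]]] = {
    "PEA": [("N1", "N"), ("C1", "C"), ("C2", "C"), ("C3", "C"), ("C4", "C"),
            ("C5", "C"), ("C6", "C"), ("C7", "C"), ("C8", "C")],
    "TYM": [("N1", "N"), ("C1", "C"), ("C2", "C"), ("C3", "C"), ("C4", "C"),
            ("C5", "C"), ("C6", "C"), ("C7", "C"), ("C8", "C"), ("O1", "O")],
    "PUT": [("N1", "N"), ("C1", "C"), ("C2", "C"), ("C3", "C"), ("C4", "C"),
            ("N2", "N")],
    "CAD": [("N1", "N"), ("C1", "C"), ("C2", "C"), ("C3", "C"), ("C4", "C"),
            ("C5", "C"), ("N2", "N")],
    "ABU": [("N1", "N"), ("C1", "C"), ("C2", "C"), ("C3", "C"), ("C4", "C"),
            ("O1", "O"), ("O2", "O")],
}

#: Atoms able to anchor a planted hydrogen bond, per ligand.  Diamines
#: bridge two aspartates via their two nitrogens; tyramine via its amine
#: and hydroxyl; single-amine ligands cannot bridge.
BRIDGE_ATOMS: dict[str, list[str]] = {
    "PEA": ["N1"],
    "TYM": ["N1", "O1"],
    "PUT": ["N1", "N2"],
    "CAD": ["N1", "N2"],
    "ABU": ["N1"],
}


class GeometryError(RuntimeError):
    """Ligand placement could not satisfy the planted contact state."""


@dataclass(frozen=True)
class ContactModel:
    """Joint Bernoulli model over K <= 3 target residues.

    ``residues`` pairs author residue numbers with generic numbers;
    ``pairwise_joints`` maps frozensets of residue numbers to the
    probability of simultaneous contact.  The triple joint defaults to
    zero (the study found no triplet simultaneity).  Frechet feasibility
    is checked on construction.
    """

    residues: tuple[tuple[int, str], ...]
    marginals: tuple[float, ...]
    pairwise_joints: Mapping[frozenset, float] = field(default_factory=dict)
    triple_joint: float = 0.0

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.marginals):
            raise ValueError("one marginal per residue required")
        if len(self.residues) > 3:
            raise ValueError("at most 3 target residues")
        for p in self.marginals:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal {p} outside [0, 1]")
        p_of = {r: p for (r, _), p in zip(self.residues, self.marginals)}
        for pair, q in self.pairwise_joints.items():
            pi, pj = (p_of[r] for r in sorted(pair))
            lo, hi = max(0.0, pi + pj - 1.0), min(pi, pj)
            if not lo - 1e-12 <= q <= hi + 1e-12:
                raise ValueError(
                    f"joint {q} for pair {sorted(pair)} violates Frechet "
                    f"bounds [{lo:.4g}, {hi:.4g}]"
                )
        self.cell_probabilities()  # raises on an infeasible joint table

    @property
    def k(self) -> int:
        return len(self.residues)

    def joint(self, pair: frozenset) -> float:
        return float(self.pairwise_joints.get(frozenset(pair), 0.0))

    def cell_probabilities(self) -> dict[tuple[int, ...], float]:
        """Explicit probability of each binary contact state (inclusion-exclusion)."""
        k = self.k
        p = self.marginals
        nums = [r for r, _ in self.residues]
        cells: dict[tuple[int, ...], float] = {}
        if k == 0:
            return {(): 1.0}
        if k == 1:
            cells = {(1,): p[0], (0,): 1 - p[0]}
        elif k == 2:
            q = self.joint(frozenset(nums))
            cells = {
                (1, 1): q,
                (1, 0): p[0] - q,
                (0, 1): p[1] - q,
                (0, 0): 1 - p[0] - p[1] + q,
            }
        else:
            q12 = self.joint(frozenset(nums[:2]))
            q13 = self.joint(frozenset((nums[0], nums[2])))
            q23 = self.joint(frozenset(nums[1:]))
            t = self.triple_joint
            cells = {
                (1, 1, 1): t,
                (1, 1, 0): q12 - t,
                (1, 0, 1): q13 - t,
                (0, 1, 1): q23 - t,
                (1, 0, 0): p[0] - q12 - q13 + t,
                (0, 1, 0): p[1] - q12 - q23 + t,
                (0, 0, 1): p[2] - q13 - q23 + t,
                (0, 0, 0): 1 - p[0] - p[1] - p[2] + q12 + q13 + q23 - t,
            }
        for state, prob in cells.items():
            if prob < -1e-12:
                raise ValueError(
                    f"infeasible joint table: state {state} has probability "
                    f"{prob:.4g} < 0"
                )
        return {s: max(0.0, v) for s, v in cells.items()}


def sample_contact_states(
    model: ContactModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw an n x K binary matrix i.i.d. from the joint contact table."""
    cells = model.cell_probabilities()
    states = list(cells)
    probs = np.array([cells[s] for s in states])
    probs = probs / probs.sum()
    idx = rng.choice(len(states), size=n, p=probs)
    return np.array([states[i] for i in idx], dtype=np.uint8)


@dataclass(frozen=True)
class ScaffoldSpec:
    """Idealised 7-helix receptor scaffold parameters (Angstrom units)."""

    bw: BWMap
    asp_positions: tuple[str, ...]  # generic numbers, e.g. ("2.50", "3.32")
    chain_id: str = "A"
    residues_per_helix: int = 30
    ring_radius: float = 11.0
    helix_radius: float = 2.3
    rise_per_residue: float = 1.5
    turn_per_residue_deg: float = 100.0

    def __post_init__(self) -> None:
        for (start, end) in self.bw.helix_ranges:
            if end - start + 1 != self.residues_per_helix:
                raise ValueError(
                    "helix ranges must match residues_per_helix "
                    f"({self.residues_per_helix}), got ({start}, {end})"
                )
        for g in self.asp_positions:
            bw_inverse(self.bw, g)  # raises if unresolvable


def build_scaffold(
    spec: ScaffoldSpec, jitter_sd: float = 0.0, rng: np.random.Generator | None = None
) -> tuple[list[AtomRecord], BWMap]:
    """Build the receptor half of a pose: 7 ideal helices on a ring.

    Non-aspartate residues carry a single C-alpha; each designated Asp
    additionally carries CB/CG/OD1/OD2 pseudo-sidechain atoms pointing at
    the central pore axis.  ``jitter_sd`` adds per-residue isotropic
    Gaussian displacement (rigid within a residue), used to make the
    structural models distinct.
    """
    asp_residues = {bw_inverse(spec.bw, g) for g in spec.asp_positions}
    atoms: list[AtomRecord] = []
    serial = 0
    rng = rng or np.random.default_rng(0)
    for h, (start, end) in enumerate(spec.bw.helix_ranges):
        angle0 = 2 * np.pi * h / 7
        centre = spec.ring_radius * np.array([np.cos(angle0), np.sin(angle0), 0.0])
        for k, resnum in enumerate(range(start, end + 1)):
            phi = np.radians(spec.turn_per_residue_deg) * k
            ca = centre + np.array(
                [
                    spec.helix_radius * np.cos(phi),
                    spec.helix_radius * np.sin(phi),
                    spec.rise_per_residue * k,
                ]
            )
            offset = (
                rng.normal(0.0, jitter_sd, size=3) if jitter_sd > 0 else np.zeros(3)
            )
            ca = ca + offset
            is_asp = resnum in asp_residues
            resname = "ASP" if is_asp else "ALA"
            serial += 1
            atoms.append(
                AtomRecord(serial, "CA", "C", resname, resnum, spec.chain_id,
                           tuple(ca), False)
            )
            if is_asp:
                # pore-ward direction: from the CA toward the bundle axis
                u = -np.array([ca[0], ca[1], 0.0])
                u = u / np.linalg.norm(u)
                z = np.array([0.0, 0.0, 1.0])
                side = {
                    "CB": ca + 1.53 * u,
                    "CG": ca + 2.5 * u,
                    "OD1": ca + 3.6 * u + 1.1 * z,
                    "OD2": ca + 3.6 * u - 1.1 * z,
                }
                for name, xyz in side.items():
                    serial += 1
                    atoms.append(
                        AtomRecord(serial, name, name[0], "ASP", resnum,
                                   spec.chain_id, tuple(xyz), False)
                    )
    return atoms, spec.bw


def _od1_position(receptor_atoms: Sequence[AtomRecord], residue: int) -> np.ndarray:
    for a in receptor_atoms:
        if a.residue_number == residue and a.atom_name == "OD1":
            return np.asarray(a.coords)
    raise ValueError(f"residue {residue} has no planted carboxylate")


def _polar_atoms(receptor_atoms: Sequence[AtomRecord], residue: int) -> np.ndarray:
    pts = [
        np.asarray(a.coords)
        for a in receptor_atoms
        if a.residue_number == residue and a.element in ("O", "N")
    ]
    return np.array(pts)


def realize_pose(
    receptor_atoms: Sequence[AtomRecord],
    ligand: str,
    state: Sequence[int],
    target_residues: Sequence[int],
    criteria: HBondCriteria = HBondCriteria(),
    rng: np.random.Generator | None = None,
    max_tries: int = 50,
) -> ComplexPose:
    """Place ligand atoms to realise a planted contact state exactly.

    For each contacted residue a donor-capable ligand atom is put at a
    uniform distance in [2.7, cutoff - 0.1] A from the residue's OD1;
    for each non-contacted target residue every ligand atom stays at
    least ``cutoff + 1`` A from the residue's O/N atoms.  A state asking
    for more simultaneous contacts than the ligand has donor-capable
    atoms is an error.
    """
    if ligand not in LIGAND_TEMPLATES:
        raise ValueError(f"unknown ligand {ligand!r}")
    if len(state) != len(target_residues):
        raise ValueError("state length must match target residues")
    rng = rng or np.random.default_rng(0)
    template = LIGAND_TEMPLATES[ligand]
    bridges = BRIDGE_ATOMS[ligand]
    contacts = [r for r, s in zip(target_residues, state) if s]
    if len(contacts) > len(bridges):
        raise GeometryError(
            f"{ligand} has {len(bridges)} donor-capable atom(s); cannot form "
            f"{len(contacts)} simultaneous contacts"
        )
    cutoff = criteria.max_da_distance
    keepout = cutoff + 1.0
    noncontacts = [r for r, s in zip(target_residues, state) if not s]
    keepout_pts = [
        _polar_atoms(receptor_atoms, r) for r in noncontacts if len(
            _polar_atoms(receptor_atoms, r))
    ]
    pore_z = float(
        np.mean([_od1_position(receptor_atoms, r)[2] for r in target_residues])
    ) if target_residues else 20.0

    for _ in range(max_tries):
        coords = _place_ligand(
            receptor_atoms, template, bridges, contacts, cutoff, pore_z, rng
        )
        if _valid(coords, keepout_pts, keepout):
            break
    else:
        raise GeometryError(
            f"could not satisfy contact state {tuple(state)} for {ligand} "
            f"after {max_tries} placements"
        )
    ligand_atoms = [
        AtomRecord(i + 1, name, elem, ligand, 900, "L", tuple(xyz), True)
        for i, ((name, elem), xyz) in enumerate(zip(template, coords))
    ]
    return ComplexPose(
        receptor_atoms=list(receptor_atoms), ligand_atoms=ligand_atoms
    )


def _valid(
    coords: Sequence[np.ndarray], keepout_pts: list[np.ndarray], keepout: float
) -> bool:
    for pts in keepout_pts:
        for xyz in coords:
            if np.min(np.linalg.norm(pts - xyz, axis=1)) < keepout:
                return False
    return True


def _place_ligand(
    receptor_atoms: Sequence[AtomRecord],
    template: list[tuple[str, str]],
    bridges: list[str],
    contacts: list[int],
    cutoff: float,
    pore_z: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    names = [n for n, _ in template]
    coords: dict[str, np.ndarray] = {}

    def anchor_point(residue: int) -> np.ndarray:
        od1 = _od1_position(receptor_atoms, residue)
        v = -np.array([od1[0], od1[1], 0.0])
        v = v / np.linalg.norm(v)
        d = rng.uniform(2.7, cutoff - 0.1)
        return od1 + d * v

    if not contacts:
        # park the whole ligand on the pore axis, well away from all helices
        z0 = pore_z + rng.uniform(-2.0, 2.0)
        return [
            np.array([0.0, 0.0, z0 + 1.2 * i]) for i in range(len(template))
        ]
    if len(contacts) == 1:
        a = anchor_point(contacts[0])
        coords[bridges[0]] = a
        centre = np.array([0.0, 0.0, a[2]])
        w = centre - a
        dist = np.linalg.norm(w)
        w = w / dist
        rest = [n for n in names if n != bridges[0]]
        pts = []
        for i, n in enumerate(rest, start=1):
            travel = 1.4 * i
            if travel <= dist:
                coords[n] = a + travel * w
            else:  # continue up the pore axis once the centre is reached
                coords[n] = centre + np.array([0.0, 0.0, travel - dist])
        return [coords[n] for n in names]
    # two simultaneous contacts: bridge atoms at both anchors, the rest of
    # the chain strung along the connecting segment
    a1 = anchor_point(contacts[0])
    a2 = anchor_point(contacts[1])
    coords[bridges[0]] = a1
    coords[bridges[1]] = a2
    interior = [n for n in names if n not in (bridges[0], bridges[1])]
    for i, n in enumerate(interior, start=1):
        frac = i / (len(interior) + 1)
        coords[n] = a1 + frac * (a2 - a1)
    return [coords[n] for n in names]


# ---------------------------------------------------------------------------
# study configuration and enumeration


@dataclass(frozen=True)
class ReceptorConfig:
    name: str
    chain: str
    bw: BWMap
    pocket_asp: Mapping[int, str]  # residue number -> generic number
    pockets: Mapping[str, tuple[int, ...]]

    def pocket_spec(self, label: str) -> PocketSpec:
        residues = {r: self.pocket_asp[r] for r in self.pockets[label]}
        return PocketSpec(label=label, residues=residues)


@dataclass(frozen=True)
class StudyConfig:
    receptors: Mapping[str, ReceptorConfig]
    ligands: tuple[str, ...]
    models: int
    replicates: int
    poses_per_run: int
    contacts: Mapping
    scaffold: Mapping

    @property
    def pocket_labels(self) -> tuple[str, ...]:
        first = next(iter(self.receptors.values()))
        return tuple(first.pockets)


def load_study_config(path: str | Path | None = None) -> StudyConfig:
    """Load the study configuration (packaged default when no path given)."""
    if path is None:
        text = resources.files("taarsite.data").joinpath("receptors.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    receptors = {}
    for name, rc in raw["receptors"].items():
        receptors[name] = ReceptorConfig(
            name=name,
            chain=rc.get("chain", "A"),
            bw=BWMap.from_config(rc["helices"]),
            pocket_asp={int(k): str(v) for k, v in rc["pocket_asp"].items()},
            pockets={k: tuple(v) for k, v in rc["pockets"].items()},
        )
    return StudyConfig(
        receptors=receptors,
        ligands=tuple(raw["ligands"]),
        models=int(raw["design"]["models"]),
        replicates=int(raw["design"]["replicates"]),
        poses_per_run=int(raw["design"]["poses_per_run"]),
        contacts=raw["contacts"],
        scaffold=raw["scaffold"],
    )


def build_contact_model(
    config: StudyConfig, receptor: str, ligand: str, pocket: str, model_id: int
) -> ContactModel:
    """The planted contact statistics for one design cell.

    Pocket-constrained cells get the base marginals and the configured
    pairwise joints for pairs inside the pocket; the unconstrained
    control gets weak marginals over all three aspartates and nonzero
    joints only in the configured model subset.
    """
    rc = config.receptors[receptor]
    contacts = config.contacts
    factor = float(contacts["ligand_factor"][ligand])
    unconstrained = len(rc.pockets[pocket]) == 0
    if unconstrained:
        residues = tuple(sorted(rc.pocket_asp))
        marg_table = contacts["unconstrained_marginal"]
    else:
        residues = tuple(sorted(rc.pockets[pocket]))
        marg_table = contacts["base_marginal"]
    gn = {r: rc.pocket_asp[r] for r in residues}
    marginals = tuple(
        min(1.0, float(marg_table[gn[r]]) * factor) for r in residues
    )
    joints: dict[frozenset, float] = {}
    if unconstrained:
        table = contacts.get("unconstrained_joints", {}).get(receptor, {}).get(
            ligand, {}
        )
        for pair_label, entry in table.items():
            if model_id in entry["models"]:
                pair = _pair_from_label(pair_label, rc)
                joints[pair] = float(entry["q"]) * factor
    else:
        table = contacts.get("joints", {}).get(receptor, {}).get(ligand, {})
        for pair_label, q in table.items():
            pair = _pair_from_label(pair_label, rc)
            if pair <= frozenset(residues):
                joints[pair] = float(q)
    return ContactModel(
        residues=tuple((r, gn[r]) for r in residues),
        marginals=marginals,
        pairwise_joints=joints,
    )


def _pair_from_label(label: str, rc: ReceptorConfig) -> frozenset:
    gens = label.split("+")
    inv = {v: k for k, v in rc.pocket_asp.items()}
    return frozenset(inv[g] for g in gens)


def condition_seed(root_seed: int, key: ConditionKey) -> int:
    """Stable per-condition seed derived from the root seed (< 2^31)."""
    text = f"{root_seed}|{key.receptor}|{key.model_id}|{key.ligand}|{key.pocket}|{key.replicate}"
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _model_scaffold(
    config: StudyConfig, receptor: str, model_id: int, seed: int
) -> list[AtomRecord]:
    rc = config.receptors[receptor]
    sc = config.scaffold
    spec = ScaffoldSpec(
        bw=rc.bw,
        asp_positions=tuple(rc.pocket_asp[r] for r in sorted(rc.pocket_asp)),
        chain_id=rc.chain,
        residues_per_helix=int(sc["residues_per_helix"]),
        ring_radius=float(sc["ring_radius"]),
        helix_radius=float(sc["helix_radius"]),
        rise_per_residue=float(sc["rise_per_residue"]),
        turn_per_residue_deg=float(sc["turn_per_residue_deg"]),
    )
    jitter = float(sc.get("model_jitter_sd", 0.0)) if model_id > 1 else 0.0
    rng = np.random.default_rng(
        condition_seed(seed, ConditionKey(receptor, model_id, "PEA", "BP_1", 1))
        ^ 0x5CAFF01D
    )
    atoms, _ = build_scaffold(spec, jitter_sd=jitter, rng=rng)
    return atoms


def iter_study_poses(
    config: StudyConfig | None = None,
    seed: int = 0,
    receptors: Sequence[str] | None = None,
    criteria: HBondCriteria = HBondCriteria(),
    poses_per_run: int | None = None,
) -> Iterator[tuple[ConditionKey, int, tuple[int, ...], ComplexPose]]:
    """Yield every pose of the study design with its planted state.

    Yields ``(condition, pose_index, state, pose)`` in deterministic
    design order (model, ligand, pocket, replicate, pose).
    """
    config = config or load_study_config()
    n_poses = poses_per_run or config.poses_per_run
    for receptor in receptors or config.receptors:
        scaffolds = {
            m: _model_scaffold(config, receptor, m, seed)
            for m in range(1, config.models + 1)
        }
        for model_id in range(1, config.models + 1):
            for ligand in config.ligands:
                for pocket in config.receptors[receptor].pockets:
                    cm = build_contact_model(config, receptor, ligand, pocket, model_id)
                    for rep in range(1, config.replicates + 1):
                        key = ConditionKey(receptor, model_id, ligand, pocket, rep)
                        rng = np.random.default_rng(condition_seed(seed, key))
                        states = sample_contact_states(cm, n_poses, rng)
                        targets = [r for r, _ in cm.residues]
                        for k in range(n_poses):
                            pose = realize_pose(
                                scaffolds[model_id],
                                ligand,
                                states[k],
                                targets,
                                criteria=criteria,
                                rng=rng,
                            )
                            pose.pose_id = (
                                f"{receptor}_m{model_id}_{ligand}_{pocket}_r{rep}_p{k + 1}"
                            )
                            pose.condition = key
                            yield key, k + 1, tuple(int(s) for s in states[k]), pose


def generate_study(
    out_dir: str | Path,
    config: StudyConfig | None = None,
    seed: int = 0,
    receptors: Sequence[str] | None = None,
    poses_per_run: int | None = None,
) -> Path:
    """Write the full study to disk and return the manifest path.

    Layout: ``<receptor>/model_<m>/<ligand>/<pocket>/rep_<r>/pose_<k>.pdb``
    with a ``manifest.tsv`` row per file carrying the condition key, the
    planted contact state and the relative path.
    """
    config = config or load_study_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.tsv"
    rows = ["receptor\tmodel_id\tligand\tpocket\treplicate\tpose\ttargets\tstate\tpath"]
    for key, k, state, pose in iter_study_poses(
        config, seed, receptors, poses_per_run=poses_per_run
    ):
        rel = Path(
            key.receptor,
            f"model_{key.model_id}",
            key.ligand,
            key.pocket,
            f"rep_{key.replicate}",
            f"pose_{k}.pdb",
        )
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.exists():
            raise FileExistsError(f"filesystem collision: {path}")
        path.write_text(write_complex(pose))
        cm_targets = ",".join(
            str(r) for r, _ in build_contact_model(
                config, key.receptor, key.ligand, key.pocket, key.model_id
            ).residues
        )
        rows.append(
            "\t".join(
                [
                    key.receptor,
                    str(key.model_id),
                    key.ligand,
                    key.pocket,
                    str(key.replicate),
                    str(k),
                    cm_targets,
                    ",".join(map(str, state)),
                    str(rel),
                ]
            )
        )
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
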