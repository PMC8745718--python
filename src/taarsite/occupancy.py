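"""Ensemble occupancy statistics over per-pose hydrogen-bond sets.

Each docked pose reduces to the set of receptor residues it hydrogen
bonds; an ensemble of poses then yields

* marginal occupancy — the fraction of poses bonding a given residue,
* joint occupancy (simultaneity) — the fraction of poses bonding every
  residue of a pair or triplet at once,
* a per-receptor frequency table over all poses and all residues ever
  bonded, and
* a binding-site classification: a residue pair is called a site for a
  ligand when its joint occupancy is observed (above a configurable
  floor) in sufficiently many independent receptor models.

The estimation side is also exposed statsmodels-style as
:class:`ContactOccupancyModel` / :class:`ContactOccupancyResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Hashable, Iterable, Mapping, Sequence

__all__ = [
    "ConditionKey",
    "PocketSpec",
    "OccupancyTable",
    "SiteCall",
    "ClassificationRule",
    "marginal_occupancy",
    "joint_occupancy",
    "frequency_table",
    "classify_sites",
    "ContactOccupancyModel",
    "ContactOccupancyResults",
]

Residue = Hashable
BondSet = frozenset


@dataclass(frozen=True, order=True)
class ConditionKey:
    """One cell of the study design: receptor model x ligand x pocket x replicate."""

    receptor: str
    model_id: int
    ligand: str
    pocket: str
    replicate: int

    def __post_init__(self) -> None:
        if not 1 <= self.model_id:
            raise ValueError("model_id must be >= 1")
        if not 1 <= self.replicate:
            raise ValueError("replicate must be >= 1")


@dataclass(frozen=True)
class PocketSpec:
    """A docking pocket: 0 (unconstrained), 2 or 3 targeted Asp residues.

    ``residues`` maps author residue number to its generic (Ballesteros–
    Weinstein) number string, e.g. ``{102: "3.32"}``.
    """

    label: str
    residues: Mapping[int, str]

    def __post_init__(self) -> None:
        if len(self.residues) not in (0, 2, 3):
            raise ValueError("pocket holds 0, 2 or 3 residues")

    @property
    def residue_numbers(self) -> frozenset[int]:
        return frozenset(self.residues)


@dataclass
class OccupancyTable:
    """Marginal and joint bond frequencies with their counts."""

    n_structures: int
    marginal: dict[Residue, tuple[int, Fraction]]
    joint: dict[frozenset, tuple[int, Fraction]] = field(default_factory=dict)
    grouping: str = "pooled"

    def marginal_percent(self, residue: Residue, decimals: int = 1) -> float:
        return round(float(self.marginal[residue][1]) * 100.0, decimals)

    def joint_percent(self, residues: Iterable[Residue], decimals: int = 1) -> float:
        return round(float(self.joint[frozenset(residues)][1]) * 100.0, decimals)


def _as_bond_sets(bond_sets: Sequence[Iterable[Residue]]) -> list[frozenset]:
    return [frozenset(s) for s in bond_sets]


def marginal_occupancy(
    bond_sets: Sequence[Iterable[Residue]],
    residues: Iterable[Residue] | None = None,
) -> OccupancyTable:
    """Per-residue bond frequency across an ensemble.

    ``residues`` fixes the rows of the table (absent residues get zero);
    by default every residue ever bonded is included.  Fractions are kept
    exact (rationals); use :meth:`OccupancyTable.marginal_percent` for
    the rounded display value.
    """
    sets = _as_bond_sets(bond_sets)
    if not sets:
        raise ValueError("empty ensemble")
    n = len(sets)
    if residues is None:
        keys = sorted({r for s in sets for r in s}, key=repr)
    else:
        keys = list(residues)
    marg = {}
    for r in keys:
        count = sum(1 for s in sets if r in s)
        marg[r] = (count, Fraction(count, n))
    return OccupancyTable(n_structures=n, marginal=marg)


def joint_occupancy(
    bond_sets: Sequence[Iterable[Residue]],
    target: Iterable[Residue],
) -> tuple[int, Fraction]:
    """Count and fraction of poses bonding every residue of ``target`` at once."""
    tgt = frozenset(target)
    if len(tgt) < 2:
        raise ValueError("joint occupancy needs a pair or triplet of residues")
    sets = _as_bond_sets(bond_sets)
    if not sets:
        raise ValueError("empty ensemble")
    count = sum(1 for s in sets if tgt <= s)
    return count, Fraction(count, len(sets))


def frequency_table(
    all_poses: Sequence[tuple[ConditionKey, Iterable[Residue]]],
    receptor: str,
) -> dict[Residue, int]:
    """Integer-percent bond frequency per residue over all poses of one receptor.

    The denominator is the full pose count of the receptor (all models,
    ligands, pockets and replicates pooled); every residue ever bonded is
    a row, not only the targeted pocket aspartates.
    """
    sets = []
    for key, s in all_poses:
        if key.receptor != receptor:
            raise ValueError(
                f"mixed receptors: expected {receptor!r}, found {key.receptor!r}"
            )
        sets.append(frozenset(s))
    if not sets:
        raise ValueError("empty ensemble")
    n = len(sets)
    out: dict[Residue, int] = {}
    for r in sorted({r for s in sets for r in s}, key=repr):
        out[r] = round(100 * sum(1 for s in sets if r in s) / n)
    return out


@dataclass(frozen=True)
class ClassificationRule:
    """Site-calling rule: joint occupancy observed in enough models.

    ``min_fraction=None`` means any strictly positive joint occupancy
    counts (the default: a site is called only when simultaneous bonding
    is seen in every model).
    """

    min_models: int = 5
    min_fraction: float | None = None

    def passes(self, fraction: float) -> bool:
        if self.min_fraction is None:
            return fraction > 0.0
        return fraction >= self.min_fraction


@dataclass(frozen=True)
class SiteCall:
    """Verdict for one candidate (receptor, ligand, residue-pair) site."""

    receptor: str
    ligand: str
    site: tuple[tuple[int, str], ...]  # ((residue_number, generic_number), ...)
    support: tuple[tuple[int, float], ...]  # (model_id, joint fraction)
    called: bool


def classify_sites(
    per_model_joint: Mapping[tuple[int, frozenset], float],
    rule: ClassificationRule = ClassificationRule(),
    *,
    receptor: str = "",
    ligand: str = "",
    generic_numbers: Mapping[int, str] | None = None,
    n_models: int = 5,
) -> list[SiteCall]:
    """Call binding sites from per-model joint occupancies.

    ``per_model_joint`` maps ``(model_id, frozenset(residue_pair))`` to
    the pooled joint fraction for that model.  Every candidate pair must
    be covered in all ``n_models`` models; a missing model is an error
    (an absent measurement is not evidence of absence).
    """
    pairs = sorted({p for (_, p) in per_model_joint}, key=lambda p: sorted(p))
    gn = generic_numbers or {}
    calls = []
    for pair in pairs:
        support = []
        for m in range(1, n_models + 1):
            if (m, pair) not in per_model_joint:
                raise ValueError(f"missing model {m} for pair {sorted(pair)}")
            support.append((m, float(per_model_joint[(m, pair)])))
        n_pass = sum(1 for _, f in support if rule.passes(f))
        calls.append(
            SiteCall(
                receptor=receptor,
                ligand=ligand,
                site=tuple(sorted((r, gn.get(r, "")) for r in pair)),
                support=tuple(support),
                called=n_pass >= rule.min_models,
            )
        )
    return calls


class ContactOccupancyModel:
    """Joint Bernoulli contact model for an ensemble of docked poses.

    The data are per-pose residue bond sets; the estimands are the
    marginal contact probabilities of a designated residue panel and the
    pairwise (and triplet) simultaneity probabilities.  ``fit`` returns a
    :class:`ContactOccupancyResults` carrying point estimates, binomial
    standard errors and Wilson confidence intervals.
    """

    def __init__(
        self,
        bond_sets: Sequence[Iterable[Residue]],
        residues: Sequence[Residue],
    ) -> None:
        if not bond_sets:
            raise ValueError("empty ensemble")
        if not residues:
            raise ValueError("residue panel is empty")
        self.bond_sets = _as_bond_sets(bond_sets)
        self.residues = list(residues)
        self.nobs = len(self.bond_sets)

    @classmethod
    def from_poses(
        cls,
        poses: Iterable,
        residues: Sequence[int],
        criteria=None,
        typing=None,
        chain_id: str = "A",
    ) -> "ContactOccupancyModel":
        """Build the model by running hydrogen-bond detection on poses."""
        from .hbond import residue_bond_set

        sets = [
            {rn for (_ch, rn) in residue_bond_set(p, criteria, typing)}
            for p in poses
        ]
        return cls(sets, residues)

    def fit(self) -> "ContactOccupancyResults":
        n = self.nobs
        marg: dict[Residue, float] = {}
        for r in self.residues:
            marg[r] = sum(1 for s in self.bond_sets if r in s) / n
        joint: dict[frozenset, float] = {}
        for k in (2, 3):
            for combo in combinations(self.residues, k):
                tgt = frozenset(combo)
                joint[tgt] = sum(1 for s in self.bond_sets if tgt <= s) / n
        return ContactOccupancyResults(self, marg, joint)


def _wilson_interval(p: float, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


class ContactOccupancyResults:
    """Estimates, uncertainties and summary for a fitted occupancy model."""

    def __init__(
        self,
        model: ContactOccupancyModel,
        marginal: dict[Residue, float],
        joint: dict[frozenset, float],
    ) -> None:
        self.model = model
        self.nobs = model.nobs
        self.marginal_ = marginal
        self.joint_ = joint

    def se(self, target) -> float:
        """Binomial standard error sqrt(p(1-p)/n) of an estimate."""
        p = self._lookup(target)
        return math.sqrt(p * (1 - p) / self.nobs)

    def conf_int(self, target, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import norm

        z = float(norm.ppf(1 - alpha / 2))
        return _wilson_interval(self._lookup(target), self.nobs, z)

    def _lookup(self, target) -> float:
        if isinstance(target, (set, frozenset, tuple, list)) and not isinstance(
            target, str
        ):
            return self.joint_[frozenset(target)]
        return self.marginal_[target]

    def summary(self) -> str:
        lines = [
            "Contact occupancy estimates",
            "=" * 62,
            f"n poses: {self.nobs}",
            f"{'target':<28}{'estimate':>10}{'SE':>10}{'95% CI':>14}",
            "-" * 62,
        ]
        for r in self.model.residues:
            p = self.marginal_[r]
            lo, hi = self.conf_int(r)
            lines.append(
                f"{str(r):<28}{p:>10.4f}{self.se(r):>10.4f}  [{lo:.3f}, {hi:.3f}]"
            )
        for tgt in sorted(self.joint_, key=lambda t: (len(t), sorted(map(repr, t)))):
            p = self.joint_[tgt]
            lo, hi = self.conf_int(tgt)
            label = "+".join(str(r) for r in sorted(tgt, key=repr))
            lines.append(
                f"{label:<28}{p:>10.4f}{self.se(tgt):>10.4f}  [{lo:.3f}, {hi:.3f}]"
            )
        return "\n".join(lines)
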