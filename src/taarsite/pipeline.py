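"""Study orchestration: enumerate the design, detect bonds, aggregate, report.

The docking study is a full-factorial design (models x ligands x pocket
options x replicates x poses).  This module enumerates it, reduces every
pose to its residue bond set, aggregates marginal/joint occupancies per
(ligand, pocket) grouping, builds the per-receptor frequency table, and
calls binding sites from per-model joint occupancies, writing TSV/JSON
reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from itertools import combinations, product
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .hbond import ChemTyping, HBondCriteria, load_default_typing, residue_bond_set
from .occupancy import (
    ClassificationRule,
    ConditionKey,
    classify_sites,
    frequency_table,
    joint_occupancy,
    marginal_occupancy,
)
from .structure_io import read_complex_file
from .synthetic import StudyConfig, load_study_config

__all__ = [
    "enumerate_design",
    "analyze_bond_sets",
    "run_analysis",
    "report_summary",
    "ReportBundle",
    "SUMMARY_SCHEMA",
]


def enumerate_design(
    models: int | Sequence = 5,
    ligands: int | Sequence = 5,
    pockets: int | Sequence = 5,
    replicates: int = 3,
    poses: int = 10,
    receptor: str = "",
) -> pd.DataFrame:
    """Cartesian product of the design, one row per pose.

    Ordering is deterministic: model, ligand, pocket, replicate, pose.
    Integer arguments enumerate 1..n (ligands/pockets get generic labels).
    """

    def _seq(x, prefix):
        if isinstance(x, int):
            if x < 0:
                raise ValueError("counts must be >= 0")
            return [f"{prefix}{i}" for i in range(1, x + 1)]
        return list(x)

    model_ids = list(range(1, models + 1)) if isinstance(models, int) else list(models)
    rows = [
        {
            "receptor": receptor,
            "model_id": m,
            "ligand": lig,
            "pocket": pk,
            "replicate": r,
            "pose": k,
        }
        for m, lig, pk, r, k in product(
            model_ids,
            _seq(ligands, "ligand_"),
            _seq(pockets, "BP_"),
            range(1, replicates + 1),
            range(1, poses + 1),
        )
    ]
    return pd.DataFrame(
        rows, columns=["receptor", "model_id", "ligand", "pocket", "replicate", "pose"]
    )


@dataclass
class ReportBundle:
    """All output tables of one analysis run."""

    marginal: pd.DataFrame
    joint: pd.DataFrame
    frequency: pd.DataFrame
    site_calls: pd.DataFrame
    n_structures: dict[str, int]
    config_digest: str = ""
    seed: int | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(sep="\t", index=False, float_format="%.10g")
        self.marginal.to_csv(out / "marginal_occupancy.tsv", **kw)
        self.joint.to_csv(out / "joint_occupancy.tsv", **kw)
        self.frequency.to_csv(out / "frequency_table.tsv", **kw)
        self.site_calls.to_csv(out / "site_calls.tsv", **kw)
        _, summary = report_summary(self)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        log = {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "n_structures": self.n_structures,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))


def analyze_bond_sets(
    records: Sequence[tuple[ConditionKey, frozenset | set]],
    config: StudyConfig | None = None,
    rule: ClassificationRule = ClassificationRule(),
) -> ReportBundle:
    """Aggregate per-pose residue bond sets into the report tables.

    ``records`` holds one (condition, bond-set) entry per pose, with
    bond sets over author residue numbers.  Replicates are pooled before
    fractions are computed.
    """
    if not records:
        raise ValueError("empty manifest: no poses to analyze")
    config = config or load_study_config()
    marginal_rows, joint_rows, freq_rows, site_rows = [], [], [], []
    n_structures: dict[str, int] = {}
    receptors = sorted({k.receptor for k, _ in records})
    for receptor in receptors:
        rc = config.receptors[receptor]
        rec_records = [(k, frozenset(s)) for k, s in records if k.receptor == receptor]
        n_structures[receptor] = len(rec_records)
        # per-receptor frequency table over every residue ever bonded
        for residue, pct in frequency_table(rec_records, receptor).items():
            freq_rows.append(
                {
                    "receptor": receptor,
                    "residue": residue,
                    "generic": rc.pocket_asp.get(residue, ""),
                    "percent": pct,
                    "n": len(rec_records),
                }
            )
        # per (ligand, pocket) marginals and joints, models+replicates pooled
        for ligand in config.ligands:
            for pocket, pocket_residues in rc.pockets.items():
                sets = [
                    s
                    for k, s in rec_records
                    if k.ligand == ligand and k.pocket == pocket
                ]
                if not sets:
                    continue
                panel = sorted(pocket_residues) or sorted(rc.pocket_asp)
                table = marginal_occupancy(sets, panel)
                for r in panel:
                    count, frac = table.marginal[r]
                    marginal_rows.append(
                        {
                            "receptor": receptor,
                            "ligand": ligand,
                            "pocket": pocket,
                            "residue": r,
                            "generic": rc.pocket_asp.get(r, ""),
                            "count": count,
                            "n": len(sets),
                            "percent": round(float(frac) * 100, 1),
                        }
                    )
                for size in (2, 3):
                    for combo in combinations(panel, size):
                        count, frac = joint_occupancy(sets, combo)
                        joint_rows.append(
                            {
                                "receptor": receptor,
                                "ligand": ligand,
                                "pocket": pocket,
                                "residues": "+".join(map(str, combo)),
                                "generic": "+".join(
                                    rc.pocket_asp.get(r, "?") for r in combo
                                ),
                                "count": count,
                                "n": len(sets),
                                "percent": round(float(frac) * 100, 1),
                            }
                        )
            # site classification from pocket-constrained runs
            candidate_pairs = [
                frozenset(p) for p in combinations(sorted(rc.pocket_asp), 2)
            ]
            per_model_joint: dict[tuple[int, frozenset], float] = {}
            for pair in candidate_pairs:
                for m in range(1, config.models + 1):
                    pooled = [
                        s
                        for k, s in rec_records
                        if k.ligand == ligand
                        and k.model_id == m
                        and pair <= frozenset(rc.pockets.get(k.pocket, ()))
                    ]
                    if pooled:
                        _, frac = joint_occupancy(pooled, pair)
                        per_model_joint[(m, pair)] = float(frac)
            if per_model_joint:
                calls = classify_sites(
                    per_model_joint,
                    rule,
                    receptor=receptor,
                    ligand=ligand,
                    generic_numbers=rc.pocket_asp,
                    n_models=config.models,
                )
                for call in calls:
                    site_rows.append(
                        {
                            "receptor": receptor,
                            "ligand": ligand,
                            "site": "+".join(g for _, g in call.site),
                            "residues": "+".join(str(r) for r, _ in call.site),
                            "support": ";".join(
                                f"m{m}:{f:.4f}" for m, f in call.support
                            ),
                            "called": call.called,
                        }
                    )
    return ReportBundle(
        marginal=pd.DataFrame(marginal_rows),
        joint=pd.DataFrame(joint_rows),
        frequency=pd.DataFrame(freq_rows),
        site_calls=pd.DataFrame(site_rows),
        n_structures=n_structures,
    )


def load_manifest_bond_sets(
    study_dir: str | Path,
    criteria: HBondCriteria = HBondCriteria(),
    typing: ChemTyping | None = None,
) -> list[tuple[ConditionKey, frozenset]]:
    """Run hydrogen-bond detection over every pose listed in a manifest."""
    study = Path(study_dir)
    manifest = study / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.tsv under {study}")
    df = pd.read_csv(manifest, sep="\t")
    typing = typing or load_default_typing()
    missing = [p for p in df["path"] if not (study / p).exists()]
    if missing:
        raise FileNotFoundError(
            f"{len(missing)} pose file(s) missing, e.g. {missing[:3]}"
        )
    records = []
    for row in df.itertuples(index=False):
        key = ConditionKey(
            receptor=row.receptor,
            model_id=int(row.model_id),
            ligand=row.ligand,
            pocket=row.pocket,
            replicate=int(row.replicate),
        )
        pose = read_complex_file(study / row.path)
        bonds = {rn for (_ch, rn) in residue_bond_set(pose, criteria, typing)}
        records.append((key, frozenset(bonds)))
    return records


def run_analysis(
    study_dir: str | Path,
    out_dir: str | Path,
    config: StudyConfig | None = None,
    criteria: HBondCriteria = HBondCriteria(),
    rule: ClassificationRule = ClassificationRule(),
    seed: int | None = None,
) -> ReportBundle:
    """File-based end-to-end analysis of a generated (or docked) study."""
    config = config or load_study_config()
    records = load_manifest_bond_sets(study_dir, criteria)
    bundle = analyze_bond_sets(records, config, rule)
    digest_src = json.dumps(
        {
            "criteria": [criteria.max_da_distance, criteria.min_dha_angle,
                         criteria.use_hydrogens],
            "rule": [rule.min_models, rule.min_fraction],
            "receptors": sorted(config.receptors),
        },
        sort_keys=True,
    )
    bundle.config_digest = hashlib.sha256(digest_src.encode()).hexdigest()[:16]
    bundle.seed = seed
    bundle.write(out_dir)
    return bundle


#: Shape of the JSON summary written next to the TSV reports.
SUMMARY_SCHEMA = {
    "n_structures": dict,
    "sites": list,  # {receptor, ligand, site, residues}
    "top_residues": dict,
}


def validate_summary(summary: Mapping) -> None:
    for key, typ in SUMMARY_SCHEMA.items():
        if key not in summary:
            raise ValueError(f"summary missing key {key!r}")
        if not isinstance(summary[key], typ):
            raise ValueError(f"summary[{key!r}] must be {typ.__name__}")


def report_summary(bundle: ReportBundle) -> tuple[str, dict]:
    """Human-readable digest plus a JSON-serialisable summary."""
    called = (
        bundle.site_calls[bundle.site_calls["called"]]
        if len(bundle.site_calls)
        else bundle.site_calls
    )
    lines = [
        "Docking-ensemble binding-site analysis",
        f"structures analyzed: "
        + ", ".join(f"{r}={n}" for r, n in sorted(bundle.n_structures.items())),
    ]
    sites = []
    if len(called):
        for (receptor, ligand), grp in called.groupby(["receptor", "ligand"]):
            site_list = "; ".join(grp["site"])
            lines.append(f"{receptor} {ligand}: {site_list}")
            for _, row in grp.iterrows():
                sites.append(
                    {
                        "receptor": receptor,
                        "ligand": ligand,
                        "site": row["site"],
                        "residues": row["residues"],
                    }
                )
    else:
        lines.append("no sites called")
    top: dict[str, list] = {}
    if len(bundle.frequency):
        for receptor, grp in bundle.frequency.groupby("receptor"):
            best = grp.sort_values(["percent", "residue"], ascending=[False, True])
            top[receptor] = [
                {"residue": int(r.residue), "percent": int(r.percent)}
                for r in best.head(5).itertuples(index=False)
            ]
    summary = {"n_structures": bundle.n_structures, "sites": sites, "top_residues": top}
    validate_summary(summary)
    return "\n".join(lines), summary
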