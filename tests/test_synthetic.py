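"""Synthetic study generator: scaffold geometry, contact model, planting."""

import dataclasses

import numpy as np
import pytest

from taarsite.geometry import bw_inverse, bw_lookup
from taarsite.hbond import HBondCriteria, residue_bond_set
from taarsite.structure_io import read_complex_file
from taarsite.synthetic import (
    ContactModel,
    GeometryError,
    LIGAND_TEMPLATES,
    ScaffoldSpec,
    build_contact_model,
    build_scaffold,
    condition_seed,
    generate_study,
    realize_pose,
    sample_contact_states,
)
from taarsite.occupancy import ConditionKey


@pytest.fixture(scope="module")
def taar6_scaffold(study_config):
    rc = study_config.receptors["TAAR6"]
    spec = ScaffoldSpec(
        bw=rc.bw, asp_positions=tuple(rc.pocket_asp[r] for r in sorted(rc.pocket_asp))
    )
    atoms, bw = build_scaffold(spec)
    return atoms, bw, rc


class TestScaffold:
    def test_ca_count(self, taar6_scaffold):
        atoms, _, _ = taar6_scaffold
        assert sum(1 for a in atoms if a.atom_name == "CA") == 7 * 30

    def test_planted_carboxylates_point_into_pore(self, taar6_scaffold):
        atoms, _, rc = taar6_scaffold
        for resnum in rc.pocket_asp:
            od1 = [a for a in atoms
                   if a.residue_number == resnum and a.atom_name == "OD1"]
            assert len(od1) == 1
            ca = next(a for a in atoms
                      if a.residue_number == resnum and a.atom_name == "CA")
            # carboxylate sits 3.6 A inward of its own C-alpha
            od_r = np.hypot(*od1[0].coords[:2])
            ca_r = np.hypot(*ca.coords[:2])
            assert od_r == pytest.approx(ca_r - 3.6, abs=1e-6)

    def test_bw_self_consistency(self, taar6_scaffold):
        _, bw, rc = taar6_scaffold
        for resnum, generic in rc.pocket_asp.items():
            assert str(bw_lookup(bw, resnum)) == generic
            assert bw_inverse(bw, generic) == resnum

    def test_unresolvable_asp_position_error(self, study_config):
        rc = study_config.receptors["TAAR6"]
        with pytest.raises(ValueError):
            ScaffoldSpec(bw=rc.bw, asp_positions=("2.99",))


class TestContactModel:
    def test_frechet_upper_bound_violation(self):
        with pytest.raises(ValueError, match="Frechet"):
            ContactModel(
                residues=((1, "2.50"), (2, "3.32")),
                marginals=(0.1, 0.5),
                pairwise_joints={frozenset({1, 2}): 0.2},
            )

    def test_infeasible_triple_table(self):
        # pairwise joints exceed what the marginals can support jointly
        with pytest.raises(ValueError, match="infeasible|Frechet"):
            ContactModel(
                residues=((1, "a"), (2, "b"), (3, "c")),
                marginals=(0.3, 0.3, 0.3),
                pairwise_joints={
                    frozenset({1, 2}): 0.25,
                    frozenset({1, 3}): 0.25,
                },
            )

    def test_degenerate_always_on(self):
        cm = ContactModel(
            residues=((1, "a"), (2, "b")),
            marginals=(1.0, 1.0),
            pairwise_joints={frozenset({1, 2}): 1.0},
        )
        states = sample_contact_states(cm, 20, np.random.default_rng(0))
        assert (states == 1).all()

    def test_zero_joint_never_cooccurs(self):
        cm = ContactModel(
            residues=((1, "a"), (2, "b")),
            marginals=(0.12, 0.21),
            pairwise_joints={frozenset({1, 2}): 0.0},
        )
        states = sample_contact_states(cm, 5000, np.random.default_rng(1))
        assert not ((states[:, 0] == 1) & (states[:, 1] == 1)).any()

    def test_sampled_moments_within_3se(self):
        p1, p2, q = 0.5, 0.5, 0.25
        cm = ContactModel(
            residues=((1, "a"), (2, "b")),
            marginals=(p1, p2),
            pairwise_joints={frozenset({1, 2}): q},
        )
        n = 100_000
        states = sample_contact_states(cm, n, np.random.default_rng(2))
        for value, target in [
            (states[:, 0].mean(), p1),
            (states[:, 1].mean(), p2),
            (((states[:, 0] == 1) & (states[:, 1] == 1)).mean(), q),
        ]:
            se = np.sqrt(target * (1 - target) / n)
            assert abs(value - target) <= 3 * se


class TestRealizePose:
    def test_all_zero_state_has_no_target_contacts(self, taar6_scaffold, typing):
        atoms, _, rc = taar6_scaffold
        targets = sorted(rc.pocket_asp)
        pose = realize_pose(atoms, "CAD", (0, 0, 0), targets,
                           rng=np.random.default_rng(0))
        assert residue_bond_set(pose, HBondCriteria(), typing) == set()

    def test_diamine_bridges_pair(self, taar6_scaffold, typing):
        atoms, _, rc = taar6_scaffold
        pose = realize_pose(atoms, "CAD", (1, 1), [78, 112],
                           rng=np.random.default_rng(0))
        bonded = {rn for _, rn in residue_bond_set(pose, HBondCriteria(), typing)}
        assert {78, 112} <= bonded

    def test_single_amine_cannot_bridge(self, taar6_scaffold):
        atoms, _, _ = taar6_scaffold
        with pytest.raises(GeometryError, match="donor-capable"):
            realize_pose(atoms, "ABU", (1, 1), [78, 112],
                         rng=np.random.default_rng(0))
        with pytest.raises(GeometryError):
            realize_pose(atoms, "PEA", (1, 1), [78, 112],
                         rng=np.random.default_rng(0))

    def test_planted_states_recovered_exactly(self, taar6_scaffold, typing):
        """Geometry is strictly inside/outside the cutoff: detection == plant."""
        atoms, _, rc = taar6_scaffold
        targets = sorted(rc.pocket_asp)
        rng = np.random.default_rng(3)
        criteria = HBondCriteria()
        for _ in range(100):
            ligand = ["TYM", "PUT", "CAD"][rng.integers(3)]
            state = tuple(rng.integers(0, 2, size=3))
            if sum(state) > 2:
                continue
            pose = realize_pose(atoms, ligand, state, targets, criteria, rng)
            bonded = {rn for _, rn in residue_bond_set(pose, criteria, typing)}
            planted = {r for r, s in zip(targets, state) if s}
            assert bonded == planted


class TestStudyGeneration:
    def test_counts_and_manifest(self, tmp_path, study_config):
        cfg = dataclasses.replace(study_config, replicates=1)
        manifest = generate_study(
            tmp_path / "study", cfg, seed=5, receptors=["TAAR6"], poses_per_run=1
        )
        rows = manifest.read_text().strip().splitlines()
        # 5 models x 5 ligands x 5 pockets x 1 replicate x 1 pose
        assert len(rows) - 1 == 125
        files = list((tmp_path / "study").rglob("*.pdb"))
        assert len(files) == 125

    def test_generated_atom_count_matches_template(self, tmp_path, study_config):
        cfg = dataclasses.replace(study_config, models=1, replicates=1)
        out = tmp_path / "s"
        manifest = generate_study(out, cfg, seed=6, receptors=["TAAR6"],
                                  poses_per_run=1)
        header, *rows = manifest.read_text().strip().splitlines()
        cols = header.split("\t")
        n_receptor = 7 * 30 + 3 * 4  # CA trace + 4 sidechain atoms per Asp
        for row in rows:
            rec = dict(zip(cols, row.split("\t")))
            pose = read_complex_file(out / rec["path"])
            assert len(pose.receptor_atoms) == n_receptor
            assert len(pose.ligand_atoms) == len(LIGAND_TEMPLATES[rec["ligand"]])

    def test_same_seed_byte_identical(self, tmp_path, study_config):
        cfg = dataclasses.replace(study_config, models=2, replicates=1)
        m1 = generate_study(tmp_path / "a", cfg, seed=7, receptors=["TAAR1"],
                            poses_per_run=2)
        m2 = generate_study(tmp_path / "b", cfg, seed=7, receptors=["TAAR1"],
                            poses_per_run=2)
        assert m1.read_text() == m2.read_text()
        f1 = sorted((tmp_path / "a").rglob("*.pdb"))
        f2 = sorted((tmp_path / "b").rglob("*.pdb"))
        assert [f.read_text() for f in f1] == [f.read_text() for f in f2]

    def test_different_seed_differs(self, tmp_path, study_config):
        cfg = dataclasses.replace(study_config, models=1, replicates=1)
        m1 = generate_study(tmp_path / "a", cfg, seed=1, receptors=["TAAR1"],
                            poses_per_run=2)
        m2 = generate_study(tmp_path / "b", cfg, seed=2, receptors=["TAAR1"],
                            poses_per_run=2)
        f1 = sorted((tmp_path / "a").rglob("*.pdb"))
        f2 = sorted((tmp_path / "b").rglob("*.pdb"))
        assert [f.read_text() for f in f1] != [f.read_text() for f in f2]

    def test_condition_seed_stable_and_bounded(self):
        key = ConditionKey("TAAR1", 1, "PUT", "BP_2", 1)
        s1 = condition_seed(123, key)
        assert s1 == condition_seed(123, key)
        assert 0 <= s1 < 2**31
        assert s1 != condition_seed(124, key)


class TestDefaultContactPattern:
    def test_pea_and_gaba_have_no_joints(self, study_config):
        for receptor in ("TAAR1", "TAAR6"):
            for ligand in ("PEA", "ABU"):
                for pocket in ("BP_1", "BP_2", "BP_3", "BP_4", "BP_5"):
                    cm = build_contact_model(study_config, receptor, ligand,
                                             pocket, 1)
                    assert all(q == 0 for q in cm.pairwise_joints.values())

    def test_taar1_tyramine_no_joints(self, study_config):
        for pocket in ("BP_1", "BP_2", "BP_3", "BP_4"):
            cm = build_contact_model(study_config, "TAAR1", "TYM", pocket, 1)
            assert all(q == 0 for q in cm.pairwise_joints.values())

    def test_triplet_joint_zero_everywhere(self, study_config):
        for receptor in ("TAAR1", "TAAR6"):
            for ligand in study_config.ligands:
                cm = build_contact_model(study_config, receptor, ligand, "BP_1", 1)
                assert cm.triple_joint == 0.0

    def test_all_default_cells_frechet_feasible(self, study_config):
        for receptor in ("TAAR1", "TAAR6"):
            for ligand in study_config.ligands:
                for pocket in study_config.receptors[receptor].pockets:
                    for model in range(1, 6):
                        build_contact_model(study_config, receptor, ligand,
                                            pocket, model)
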