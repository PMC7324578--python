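"""Geometric E/H/V interaction detection on hand-built fixtures."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from simmap.interactions import (
    DockedPose,
    InteractionRecord,
    InteractionRules,
    detect_interactions,
    read_poses,
    read_scores,
    summarize_pose,
    write_poses,
    write_scores,
)
from simmap.structure import Atom, PocketDefinition, Residue, ResidueRef


def mol_from_spec(smiles: str, coords) -> Chem.Mol:
    """Molecule with explicit coordinates (order = SMILES atom order)."""
    mol = Chem.MolFromSmiles(smiles)
    mol = Chem.AddHs(mol) if "[H]" in smiles else mol
    mol = Chem.MolFromSmiles(smiles)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, c in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*map(float, c)))
    mol.AddConformer(conf)
    return mol


def single_residue_pocket(name: str, atoms) -> PocketDefinition:
    res = Residue(ResidueRef("A", 1, name), [Atom(n, e, tuple(c)) for n, e, c in atoms])
    return PocketDefinition([res])


def pose(smiles, coords, cid="x", score=-50.0):
    return DockedPose(cid, mol_from_spec(smiles, coords), score)


HIS_SIDECHAIN = [
    ("ND1", "N", (0.0, 0.0, 0.0)),
    ("CE1", "C", (1.3, 0.6, 0.0)),
    ("NE2", "N", (2.4, -0.2, 0.0)),
    ("CD2", "C", (1.9, -1.5, 0.0)),
    ("CG", "C", (0.5, -1.4, 0.0)),
]


def itypes(records):
    return {r.itype for r in records}


def test_carbonyl_near_histidine_gives_h_bond():
    # acetone O placed 2.9 A from His ND1
    p = pose("CC(C)=O", [(-6.0, 0, 0), (-4.5, 0, 0), (-4.0, 1.4, 0), (-2.9, -0.7, 0)])
    pk = single_residue_pocket("HIS", HIS_SIDECHAIN)
    recs = detect_interactions(p, pk)
    assert np.linalg.norm(np.array([-2.9, -0.7, 0])) == pytest.approx(2.983, abs=0.01)
    assert "H" in itypes(recs)
    assert "E" not in itypes(recs)  # neutral ketone


ARG_GUANIDINIUM = [
    ("NH1", "N", (0.0, 0.0, 0.0)),
    ("CZ", "C", (1.33, 0.0, 0.0)),
    ("NH2", "N", (2.0, 1.15, 0.0)),
    ("NE", "N", (2.0, -1.15, 0.0)),
]


def test_carboxylate_near_arginine_gives_e_and_h():
    # acetate O- at 3.4 A from NH1: electrostatic, and H (donor-acceptor <= 3.5)
    p = pose(
        "CC(=O)[O-]",
        [(-6.6, 0, 0), (-5.2, 0, 0), (-4.6, 1.1, 0), (-3.4, 0.0, 0)],
    )
    pk = single_residue_pocket("ARG", ARG_GUANIDINIUM)
    recs = detect_interactions(p, pk)
    assert {"E", "H"} <= itypes(recs)


def test_benzene_near_leucine_carbon_gives_v_only():
    leu = [("CD1", "C", (0.0, 0.0, 0.0)), ("CG", "C", (1.5, 0.0, 0.0))]
    ring = []
    for k in range(6):
        ang = k * np.pi / 3
        ring.append((-3.5, 1.39 * np.cos(ang), 1.39 * np.sin(ang)))
    p = pose("c1ccccc1", ring)
    recs = detect_interactions(p, single_residue_pocket("LEU", leu))
    assert itypes(recs) == {"V"}
    (rec,) = recs
    assert rec.moiety_label == "benzene ring"
    assert len(rec.ligand_atoms) >= 1


def test_tighter_cutoffs_never_create_records():
    p = pose(
        "CC(=O)[O-]",
        [(-6.6, 0, 0), (-5.2, 0, 0), (-4.6, 1.1, 0), (-3.4, 0.0, 0)],
    )
    pk = single_residue_pocket("ARG", ARG_GUANIDINIUM)
    loose = detect_interactions(p, pk, InteractionRules())
    tight = detect_interactions(
        p,
        pk,
        InteractionRules(
            hbond_distance=3.0, electrostatic_distance=3.2, vdw_slack=0.1, vdw_cap=3.5
        ),
    )
    assert {(r.residue.key, r.itype) for r in tight} <= {
        (r.residue.key, r.itype) for r in loose
    }


def test_detection_invariant_under_rigid_motion(toy, planted100, rng):
    poses, _, _ = planted100
    p = poses[0]
    pk = toy.pocket()
    base = {(r.residue.key, r.itype) for r in detect_interactions(p, pk)}
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    t = rng.normal(size=3) * 5
    mol = Chem.Mol(p.mol)
    conf = mol.GetConformer()
    for i in range(mol.GetNumAtoms()):
        v = np.array(conf.GetAtomPosition(i))
        conf.SetAtomPosition(i, Point3D(*(q @ v + t)))
    moved_pose = DockedPose(p.compound_id, mol, p.docking_score)
    moved_res = [
        Residue(
            r.ref,
            [Atom(a.name, a.element, tuple(q @ np.array(a.coord) + t)) for a in r.atoms],
        )
        for r in pk.residues
    ]
    moved_pk = PocketDefinition(moved_res)
    got = {(r.residue.key, r.itype) for r in detect_interactions(moved_pose, moved_pk)}
    assert got == base


def test_hbond_angle_filter_with_explicit_hydrogens():
    # amine donor with an explicit H: the D-H...A angle decides the bond.
    # (serine OG is the acceptor; the amine N is not an acceptor itself)
    ser = single_residue_pocket("SER", [("OG", "O", (0.0, 0.0, 0.0))])

    def methylamine(h_pos):
        mol = Chem.RWMol()
        c = mol.AddAtom(Chem.Atom(6))
        n = mol.AddAtom(Chem.Atom(7))
        h = mol.AddAtom(Chem.Atom(1))
        mol.AddBond(c, n, Chem.BondType.SINGLE)
        mol.AddBond(n, h, Chem.BondType.SINGLE)
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        conf = Chem.Conformer(3)
        conf.SetAtomPosition(c, Point3D(-4.4, 0, 0))
        conf.SetAtomPosition(n, Point3D(-3.0, 0, 0))
        conf.SetAtomPosition(h, Point3D(*h_pos))
        m.AddConformer(conf)
        return m

    toward = DockedPose("t", methylamine((-2.0, 0, 0)))  # N-H points at acceptor
    away = DockedPose("a", methylamine((-3.4, 0.9, 0)))  # N-H points away
    assert "H" in itypes(detect_interactions(toward, ser))
    assert "H" not in itypes(detect_interactions(away, ser))


def test_empty_pocket_and_no_heavy_atom_errors():
    p = pose("C", [(0, 0, 0)])
    assert detect_interactions(p, PocketDefinition([], "x")) == []
    with pytest.raises(ValueError, match="no heavy atoms"):
        mol = Chem.MolFromSmiles("[H][H]", sanitize=False)
        conf = Chem.Conformer(2)
        mol.AddConformer(conf)
        DockedPose("h2", mol)


def test_summarize_pose_rollup(toy, planted100):
    poses, _, truth = planted100
    p = poses[0]
    recs = detect_interactions(p, toy.pocket())
    flags = summarize_pose(recs)
    assert set(flags) == {(k, t) for k, t, _ in truth[p.compound_id]}
    assert all(v == 1 for v in flags.values())
    assert summarize_pose([]) == {}
    mixed = [
        InteractionRecord("a", ResidueRef("A", 1, "ALA"), "V", (0,), "x", (0, 0, 0)),
        InteractionRecord("b", ResidueRef("A", 1, "ALA"), "V", (0,), "x", (0, 0, 0)),
    ]
    with pytest.raises(ValueError, match="mix"):
        summarize_pose(mixed)


def test_pose_and_score_io_round_trip(tmp_path, planted100):
    poses, scores, _ = planted100
    sdf = tmp_path / "poses.sdf"
    tsv = tmp_path / "scores.tsv"
    write_poses(poses[:5], sdf)
    write_scores({p.compound_id: scores[p.compound_id] for p in poses[:5]}, tsv)
    back_scores = read_scores(tsv)
    back = read_poses(sdf, back_scores)
    assert [p.compound_id for p in back] == [p.compound_id for p in poses[:5]]
    for a, b in zip(back, poses[:5]):
        assert a.docking_score == pytest.approx(b.docking_score)
        np.testing.assert_allclose(a.coords(), b.coords(), atol=1e-3)
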