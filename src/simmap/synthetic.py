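"""Fully in-silico pockets, poses, profiles and screens with planted truth.

Every stage of the pipeline is testable without docking software: a toy
pocket puts minimal residues on a spherical shell around a small
reference ligand, and poses place catalog moieties at geometries that
satisfy the interaction rules at chosen residues (probability ``p_hot``)
and background residues (``p_bg``), returning the exact intended
(residue, type, moiety) sets as ground truth.

Residue templates are single amino acids with the smallest side-chain
atom set that carries the needed chemistry: an arginine guanidinium for
electrostatics, an asparagine amide for hydrogen bonds, a leucine-like
carbon cluster for van der Waals, and an alanine as inert background.
Contact fragments (formate, acetaldehyde, benzene) extend radially
inward so that only the intended residue is touched; residue directions
are icosahedron vertices, at least 63 deg apart, which keeps a fragment
placed at one residue more than 6 A away from every other residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from .interactions import DockedPose
from .profiles import InteractionProfile
from .structure import (
    Atom,
    PocketDefinition,
    ProteinStructure,
    Residue,
    ResidueRef,
    define_catalytic_site,
    write_pdb,
)

__all__ = [
    "AnchorPlan",
    "PlantedPocketSpec",
    "PlantedScreenSpec",
    "ToyPocket",
    "make_toy_pocket",
    "make_planted_poses",
    "make_planted_profile",
    "make_screen",
]

SHELL_RADIUS = 7.5  # A; inside the 8 A catalytic-site cutoff

_PHI = (1 + 5**0.5) / 2
_ICOSA = np.array(
    [
        (0, 1, _PHI), (0, -1, _PHI), (0, 1, -_PHI), (0, -1, -_PHI),
        (1, _PHI, 0), (-1, _PHI, 0), (1, -_PHI, 0), (-1, -_PHI, 0),
        (_PHI, 0, 1), (-_PHI, 0, 1), (_PHI, 0, -1), (-_PHI, 0, -1),
    ],
    dtype=float,
)
_ICOSA /= np.linalg.norm(_ICOSA, axis=1, keepdims=True)

# fragment moiety labels as the catalog names them
PLAN_MOIETY = {"E": "carboxylate", "EH": "carboxylate", "H": "aldehyde", "V": "benzene ring"}


@dataclass(frozen=True)
class AnchorPlan:
    """One planted anchor: which residues, which interaction, how often."""

    residue_indices: tuple[int, ...]
    itype: str  # E, H, V, or EH (formate close enough for both E and H)
    p_hot: float = 1.0

    def __post_init__(self) -> None:
        if self.itype not in {"E", "H", "V", "EH"}:
            raise ValueError(f"unknown plan itype {self.itype!r}")
        if not self.residue_indices:
            raise ValueError("plan needs >= 1 residue")


@dataclass
class PlantedPocketSpec:
    n_residues: int = 8
    anchor_plans: list[AnchorPlan] = field(
        default_factory=lambda: [
            AnchorPlan((0,), "EH"),
            AnchorPlan((2,), "H"),
            AnchorPlan((4, 5), "V"),
        ]
    )
    p_bg: float = 0.0
    radius: float = SHELL_RADIUS

    def __post_init__(self) -> None:
        if not 1 <= self.n_residues <= len(_ICOSA):
            raise ValueError(
                f"n_residues must be in [1, {len(_ICOSA)}] for the icosahedral layout"
            )
        used: set[int] = set()
        for plan in self.anchor_plans:
            for i in plan.residue_indices:
                if not 0 <= i < self.n_residues:
                    raise ValueError(f"plan residue index {i} out of range")
                if i in used:
                    raise ValueError(f"residue {i} appears in two plans")
                used.add(i)
            if not plan.p_hot > self.p_bg:
                raise ValueError("p_hot must exceed p_bg")

    def plan_for(self, index: int) -> AnchorPlan | None:
        for plan in self.anchor_plans:
            if index in plan.residue_indices:
                return plan
        return None


@dataclass
class ToyPocket:
    structure: ProteinStructure
    ligand: Residue
    directions: np.ndarray  # unit vectors, one per residue
    spec: PlantedPocketSpec

    def ligand_coords(self) -> np.ndarray:
        return self.ligand.heavy_coords()

    def pocket(self, cutoff: float = 8.0) -> PocketDefinition:
        return define_catalytic_site(
            self.structure, self.ligand_coords(), cutoff, reference_ligand_id="ACD"
        )

    def write(self, pdb_path: str | Path) -> None:
        write_pdb(self.structure, pdb_path, ligand=self.ligand)


def _residue_template(kind: str, number: int, u: np.ndarray, radius: float) -> Residue:
    """Minimal residue with its contact atom at ``radius * u``.

    Remaining atoms sit further out along u (or a perpendicular) so the
    contact atom is always the nearest one to the pocket centre.
    """
    v = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, v)) > 0.9:
        v = np.array([1.0, 0.0, 0.0])
    v = v - np.dot(v, u) * u
    v /= np.linalg.norm(v)
    p = lambda d, s=0.0: tuple((radius + d) * u + s * v)
    if kind == "ARG":  # guanidinium: E-capable (+), NH donor
        atoms = [
            Atom("NH1", "N", p(0.0)),
            Atom("CZ", "C", p(1.33)),
            Atom("NH2", "N", p(1.33, 1.33)),
            Atom("NE", "N", p(1.33, -1.33)),
            Atom("CD", "C", p(2.8)),
        ]
    elif kind == "ASN":  # amide: ND2 donor at shell, OD1 acceptor outward
        atoms = [
            Atom("ND2", "N", p(0.0)),
            Atom("CG", "C", p(1.33)),
            Atom("OD1", "O", p(1.33, 1.23)),
            Atom("CB", "C", p(2.8)),
        ]
    elif kind == "LEU":  # carbon cluster for van der Waals
        atoms = [
            Atom("CD1", "C", p(0.0)),
            Atom("CG", "C", p(1.5)),
            Atom("CD2", "C", p(1.5, 1.5)),
            Atom("CB", "C", p(3.0)),
        ]
    elif kind == "ALA":  # inert background
        atoms = [Atom("CB", "C", p(0.0)), Atom("CA", "C", p(1.5))]
    else:
        raise ValueError(f"unknown template {kind!r}")
    ref = ResidueRef(chain_id="A", residue_number=number, residue_name=kind)
    return Residue(ref=ref, atoms=atoms)


_PLAN_TEMPLATE = {"E": "ARG", "EH": "ARG", "H": "ASN", "V": "LEU"}


def make_toy_pocket(spec: PlantedPocketSpec | None = None) -> ToyPocket:
    """Build the planted pocket: shell residues plus a central toy ligand."""
    spec = spec or PlantedPocketSpec()
    directions = _ICOSA[: spec.n_residues]
    residues = []
    for i, u in enumerate(directions):
        plan = spec.plan_for(i)
        kind = _PLAN_TEMPLATE[plan.itype] if plan else "ALA"
        residues.append(_residue_template(kind, i + 1, u, spec.radius))
    structure = ProteinStructure(residues)
    lig_ref = ResidueRef(chain_id="L", residue_number=900, residue_name="ACD")
    ligand = Residue(
        ref=lig_ref,
        atoms=[
            Atom("C1", "C", (0.0, 0.0, 0.0)),
            Atom("C2", "C", (1.4, 0.0, 0.0)),
            Atom("C3", "C", (-0.7, 1.2, 0.0)),
        ],
    )
    return ToyPocket(structure=structure, ligand=ligand, directions=directions, spec=spec)


# -- contact fragments ---------------------------------------------------------
# Each fragment is appended to a pose molecule with its contact atom at
# distance d inward from the residue contact atom, the rest further in.


def _perp(u: np.ndarray) -> np.ndarray:
    v = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, v)) > 0.9:
        v = np.array([1.0, 0.0, 0.0])
    v = v - np.dot(v, u) * u
    return v / np.linalg.norm(v)


def _add_formate(em: Chem.RWMol, coords: list, u: np.ndarray, start: np.ndarray) -> None:
    """[O-]C(=O)H with the charged O at ``start``, chain pointing inward."""
    o1 = em.AddAtom(Chem.Atom(8))
    em.GetAtomWithIdx(o1).SetFormalCharge(-1)
    c = em.AddAtom(Chem.Atom(6))
    o2 = em.AddAtom(Chem.Atom(8))
    em.AddBond(o1, c, Chem.BondType.SINGLE)
    em.AddBond(c, o2, Chem.BondType.DOUBLE)
    coords += [start, start - 1.25 * u, start - 2.5 * u]


def _add_acetaldehyde(em: Chem.RWMol, coords: list, u: np.ndarray, start: np.ndarray) -> None:
    """CH3-CHO with the carbonyl O at ``start``."""
    o = em.AddAtom(Chem.Atom(8))
    c2 = em.AddAtom(Chem.Atom(6))
    c1 = em.AddAtom(Chem.Atom(6))
    em.AddBond(c2, o, Chem.BondType.DOUBLE)
    em.AddBond(c1, c2, Chem.BondType.SINGLE)
    coords += [start, start - 1.22 * u, start - 2.7 * u]


def _add_benzene(em: Chem.RWMol, coords: list, u: np.ndarray, center: np.ndarray) -> None:
    """Benzene ring centred at ``center`` in the plane perpendicular to u."""
    v = _perp(u)
    w = np.cross(u, v)
    idx = []
    for k in range(6):
        a = Chem.Atom(6)
        a.SetIsAromatic(True)
        idx.append(em.AddAtom(a))
        ang = k * np.pi / 3
        coords.append(center + 1.39 * (np.cos(ang) * v + np.sin(ang) * w))
    for k in range(6):
        b = em.AddBond(idx[k], idx[(k + 1) % 6], Chem.BondType.AROMATIC)
        em.GetBondWithIdx(b - 1).SetIsAromatic(True)


# contact distances (A) from the residue contact atom, chosen against the
# default InteractionRules so each fragment triggers exactly its plan type(s)
_CONTACT = {
    "EH": (_add_formate, 3.0),   # <=3.5: H fires; <=4.0: E fires
    "E": (_add_formate, 3.8),    # in (3.5, 4.0]: E only
    "H": (_add_acetaldehyde, 3.0),
    "V": (_add_benzene, 3.4),    # ring atoms ~3.68 from the contact carbon
}
_PLAN_TYPES = {"EH": ("E", "H"), "E": ("E",), "H": ("H",), "V": ("V",)}


def _build_pose(
    compound_id: str,
    placements: Sequence[tuple[str, np.ndarray]],
    docking_score: float,
) -> DockedPose:
    """Assemble one pose from (plan_itype, residue_direction) placements."""
    em = Chem.RWMol()
    coords: list[np.ndarray] = []
    if not placements:
        _add_benzene(em, coords, np.array([0.0, 0.0, 1.0]), np.zeros(3))
    for itype, u in placements:
        builder, dist = _CONTACT[itype]
        start = (SHELL_RADIUS - dist) * u
        if itype == "V":
            builder(em, coords, u, start)
        else:
            builder(em, coords, u, start)
    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, c in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*map(float, c)))
    mol.AddConformer(conf)
    mol.SetProp("_Name", compound_id)
    return DockedPose(compound_id=compound_id, mol=mol, docking_score=docking_score)


def make_planted_poses(
    toy: ToyPocket,
    n_compounds: int,
    seed: int = 0,
    score_mean: float = -80.0,
    score_sd: float = 10.0,
) -> tuple[list[DockedPose], dict[str, float], dict[str, set[tuple[str, str, str]]]]:
    """Poses with planted contacts, docking scores, and the intended truth.

    Returns ``(poses, scores, truth)`` where ``truth[compound_id]`` is
    the exact set of intended ``(residue_key, itype, moiety)`` records.
    With ``p_hot = 1`` and ``p_bg = 0`` detection recovers these sets
    identically.
    """
    spec = toy.spec
    rng = np.random.default_rng(seed)
    width = len(str(max(n_compounds, 1)))
    poses: list[DockedPose] = []
    scores: dict[str, float] = {}
    truth: dict[str, set[tuple[str, str, str]]] = {}
    residues = toy.structure.residues
    for c in range(n_compounds):
        cid = f"cpd{c + 1:0{width}d}"
        placements: list[tuple[str, np.ndarray]] = []
        intended: set[tuple[str, str, str]] = set()
        for i, res in enumerate(residues):
            plan = spec.plan_for(i)
            if plan is not None:
                if rng.random() < plan.p_hot:
                    placements.append((plan.itype, toy.directions[i]))
                    for t in _PLAN_TYPES[plan.itype]:
                        intended.add((res.ref.key, t, PLAN_MOIETY[plan.itype]))
            elif spec.p_bg > 0 and rng.random() < spec.p_bg:
                placements.append(("V", toy.directions[i]))
                intended.add((res.ref.key, "V", PLAN_MOIETY["V"]))
        score = float(rng.normal(score_mean, score_sd))
        poses.append(_build_pose(cid, placements, score))
        scores[cid] = score
        truth[cid] = intended
    return poses, scores, truth


def make_planted_profile(
    n_compounds: int,
    n_residues: int,
    hot_columns: Sequence[int],
    p_hot: float = 0.8,
    p_bg: float = 0.1,
    seed: int = 0,
    itype: str = "H",
) -> InteractionProfile:
    """Matrix-level generator: Bernoulli profile with elevated hot columns."""
    if not p_hot > p_bg:
        raise ValueError("p_hot must exceed p_bg")
    rng = np.random.default_rng(seed)
    p = np.full(n_residues, p_bg)
    p[list(hot_columns)] = p_hot
    m = (rng.random((n_compounds, n_residues)) < p).astype(np.uint8)
    residues = [ResidueRef("A", j + 1, "ALA") for j in range(n_residues)]
    ids = [f"cpd{i + 1}" for i in range(n_compounds)]
    return InteractionProfile(itype=itype, matrix=m, compound_ids=ids, residues=residues)


def make_contact_pose(
    toy: ToyPocket,
    contacts: Sequence[tuple[int, str]],
    compound_id: str = "query",
    docking_score: float = -50.0,
) -> DockedPose:
    """One pose with chosen contacts: (residue_index, kind) per fragment.

    ``kind`` picks the fragment and geometry of the planted-contact
    table: "EH" / "E" (formate), "H" (acetaldehyde), "V" (benzene).
    Useful for constructing single-interaction probes, e.g. a
    hydrogen-bond-only contact at an electrostatic-capable residue.
    """
    placements = [(kind, toy.directions[i]) for i, kind in contacts]
    return _build_pose(compound_id, placements, docking_score)


def make_analog_families(
    n_families: int = 2,
    n_members: int = 10,
    family_bits: int = 20,
    within_keep: float = 0.9,
    across_overlap: float = 0.1,
    seed: int = 0,
):
    """Planted analog families as 90-bit moiety fingerprints.

    Each family has a support of ``family_bits`` bits; supports of
    different families share ``across_overlap * family_bits`` bits.
    A member keeps each support bit with probability ``within_keep``.
    Returns ``(fingerprints, labels)`` with labels mapping compound id
    to family index.
    """
    from .moieties import MoietyFingerprint, N_BITS, load_catalog

    rng = np.random.default_rng(seed)
    n_shared = int(round(across_overlap * family_bits))
    n_own = family_bits - n_shared
    if n_shared + n_families * n_own > N_BITS:
        raise ValueError("families do not fit in the fingerprint length")
    shared = list(range(n_shared))
    version = load_catalog().version
    fps, labels = [], {}
    for fam in range(n_families):
        own = list(range(n_shared + fam * n_own, n_shared + (fam + 1) * n_own))
        support = shared + own
        for m in range(n_members):
            bits = [0] * N_BITS
            for b in support:
                if rng.random() < within_keep:
                    bits[b] = 1
            cid = f"fam{fam}_m{m:02d}"
            fps.append(MoietyFingerprint(cid, tuple(bits), version))
            labels[cid] = fam
    return fps, labels


@dataclass
class PlantedScreenSpec:
    """Active/decoy screen: binders hit every planted anchor, decoys none.

    Score distributions default to identical normals for both classes so
    that any enrichment can only come from the anchor terms.
    """

    n_binders: int = 10
    n_decoys: int = 90
    binder_score_mean: float = -80.0
    binder_score_sd: float = 10.0
    decoy_score_mean: float = -80.0
    decoy_score_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.n_binders < 1 or self.n_decoys < 0:
            raise ValueError("need >= 1 binder and >= 0 decoys")


def make_screen(
    toy: ToyPocket, spec: PlantedScreenSpec, seed: int = 0
) -> tuple[list[DockedPose], dict[str, float], list[str]]:
    """Screening library: returns (poses, scores, binder ids)."""
    rng = np.random.default_rng(seed)
    n = spec.n_binders + spec.n_decoys
    width = len(str(n))
    poses: list[DockedPose] = []
    scores: dict[str, float] = {}
    binder_ids: list[str] = []
    order = rng.permutation(n)  # interleave classes in id space
    for slot, is_binder in enumerate(order < spec.n_binders):
        cid = f"lib{slot + 1:0{width}d}"
        if is_binder:
            placements = [
                (plan.itype, toy.directions[i])
                for plan in toy.spec.anchor_plans
                for i in plan.residue_indices
            ]
            score = float(rng.normal(spec.binder_score_mean, spec.binder_score_sd))
            binder_ids.append(cid)
        else:
            placements = []
            score = float(rng.normal(spec.decoy_score_mean, spec.decoy_score_sd))
        poses.append(_build_pose(cid, placements, score))
        scores[cid] = score
    return poses, scores, binder_ids
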