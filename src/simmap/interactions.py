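"""Per-pose protein-ligand interaction detection (E / H / V).

Docking engines score electrostatic, hydrogen-bond and van der Waals
terms internally; here the three interaction types are re-detected from
pose geometry with standard structural-biology cutoffs so that any
docking program's poses can feed a site-moiety map:

* **H** (hydrogen bond) - donor/acceptor heavy-atom distance <= 3.5 A;
  when the ligand donor carries explicit hydrogens, the D-H...A angle
  must also be >= 120 deg (distance-only otherwise, e.g. for poses
  without hydrogens).
* **E** (electrostatic) - oppositely charged groups with closest
  heavy-atom distance <= 4.0 A. Charged groups cover formal charges
  plus the usual physiological-pH ionisations (carboxylate, sulfonate,
  phosphate, aliphatic amines, guanidinium) and the His/Lys/Arg/
  Asp/Glu side chains.
* **V** (van der Waals) - any heavy-atom pair within the sum of van
  der Waals radii + 0.5 A (capped at 4.5 A), excluding atom pairs
  already attributed to an H or E contact.

All cutoffs live in :class:`InteractionRules` and may be overridden
from YAML. Contacts are rolled up to one record per (residue, type);
E and H may co-occur on the same residue. Histidine is treated as
donor, acceptor and positively chargeable.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from rdkit import Chem
from scipy.spatial.distance import cdist

from .moieties import label_fragment
from .structure import PocketDefinition, Residue, ResidueRef

__all__ = [
    "InteractionRules",
    "DockedPose",
    "InteractionRecord",
    "detect_interactions",
    "summarize_pose",
    "read_poses",
    "read_scores",
    "write_poses",
    "write_scores",
]

ITYPES = ("E", "H", "V")


@dataclass(frozen=True)
class InteractionRules:
    """Geometric criteria; distances in Angstrom, angles in degrees."""

    hbond_distance: float = 3.5
    hbond_angle: float = 120.0
    electrostatic_distance: float = 4.0
    vdw_slack: float = 0.5
    vdw_cap: float = 4.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InteractionRules":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DockedPose:
    """A single docked conformation of one compound."""

    compound_id: str
    mol: Chem.Mol
    docking_score: float = 0.0

    def __post_init__(self) -> None:
        if self.mol is None:
            raise ValueError(f"pose {self.compound_id!r}: molecule is unparseable")
        if self.mol.GetNumConformers() == 0:
            raise ValueError(f"pose {self.compound_id!r}: no 3D coordinates")
        if self.heavy_atom_count == 0:
            raise ValueError(f"pose {self.compound_id!r}: no heavy atoms")

    @property
    def heavy_atom_count(self) -> int:
        """Heavy-atom count M used in the M**0.5 size penalty."""
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1)

    def heavy_atom_indices(self) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]

    def coords(self) -> np.ndarray:
        return self.mol.GetConformer().GetPositions()


@dataclass(frozen=True)
class InteractionRecord:
    compound_id: str
    residue: ResidueRef
    itype: str
    ligand_atoms: tuple[int, ...]
    moiety_label: str
    contact_point: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.itype not in ITYPES:
            raise ValueError(f"itype must be one of {ITYPES}, got {self.itype!r}")
        if not self.ligand_atoms:
            raise ValueError("ligand_atoms must be non-empty")
        if not all(math.isfinite(v) for v in self.contact_point):
            raise ValueError("contact_point must be finite")


# -- protein-side chemistry tables --------------------------------------------

# backbone N is a donor (except proline), backbone O/OXT acceptors
_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "HIS": {"ND1", "NE2"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "TRP": {"NE1"}, "CYS": {"SG"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"OD1"}, "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
# charged side-chain groups: (sign, atom names)
_CHARGED_GROUPS = {
    "LYS": (+1, {"NZ"}),
    "ARG": (+1, {"NE", "CZ", "NH1", "NH2"}),
    "HIS": (+1, {"ND1", "CE1", "NE2", "CD2", "CG"}),
    "ASP": (-1, {"CG", "OD1", "OD2"}),
    "GLU": (-1, {"CD", "OE1", "OE2"}),
}

_VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "FE": 2.00, "ZN": 1.39,
}
_VDW_DEFAULT = 1.70


def _vdw(element: str) -> float:
    return _VDW_RADII.get(element.upper(), _VDW_DEFAULT)


class _ResidueChemistry:
    """Heavy atoms of one pocket residue with donor/acceptor/charge roles."""

    def __init__(self, res: Residue):
        self.ref = res.ref
        heavy = [a for a in res.atoms if a.is_heavy]
        self.names = [a.name for a in heavy]
        self.elements = [a.element.upper() for a in heavy]
        self.coords = np.array([a.coord for a in heavy], dtype=float).reshape(-1, 3)
        self.radii = np.array([_vdw(e) for e in self.elements])
        name = res.ref.residue_name
        donors = set(_SIDECHAIN_DONORS.get(name, set()))
        if name != "PRO":
            donors.add("N")
        acceptors = set(_SIDECHAIN_ACCEPTORS.get(name, set())) | {"O", "OXT"}
        self.donor_idx = [i for i, n in enumerate(self.names) if n in donors]
        self.acceptor_idx = [i for i, n in enumerate(self.names) if n in acceptors]
        charged = _CHARGED_GROUPS.get(name)
        self.charge_sign = charged[0] if charged else 0
        self.charged_idx = (
            [i for i, n in enumerate(self.names) if n in charged[1]] if charged else []
        )


# ionizable ligand groups: (SMARTS, sign)
_LIGAND_CHARGE_PATTERNS = [
    ("[CX3](=[OX1])[OX2H1,OX1-]", -1),          # carboxylic acid / carboxylate
    ("[SX4](=[OX1])(=[OX1])[OX2H1,OX1-]", -1),  # sulfonic acid / sulfonate
    ("[PX4](=[OX1])([OX2H1,OX1-])[OX2H1,OX1-]", -1),  # phosphate/phosphonate head
    ("[NX3;H2,H1,H0;!$([N][CX3]=[OX1,SX1,NX2]);!$([N]a);!$([N]=*)][CX4]", +1),  # aliphatic amine
    ("[NX4+]", +1),
    ("[NX3][CX3](=[NX2])[NX3]", +1),            # guanidinium
]
_ligand_charge_patterns = [
    (Chem.MolFromSmarts(s), sign) for s, sign in _LIGAND_CHARGE_PATTERNS
]


class _LigandChemistry:
    """Donor/acceptor/charged-group assignment for a pose's molecule."""

    def __init__(self, pose: DockedPose):
        mol = pose.mol
        self.coords_all = pose.coords()
        self.heavy = pose.heavy_atom_indices()
        self.coords = self.coords_all[self.heavy]
        self.radii = np.array(
            [_vdw(mol.GetAtomWithIdx(i).GetSymbol()) for i in self.heavy]
        )
        self.donors: list[int] = []    # atom indices (molecule numbering)
        self.acceptors: list[int] = []
        for i in self.heavy:
            atom = mol.GetAtomWithIdx(i)
            z = atom.GetAtomicNum()
            if (
                z in (7, 8, 16)
                and atom.GetTotalNumHs(includeNeighbors=True) >= 1
                and atom.GetFormalCharge() >= 0
            ):
                self.donors.append(i)
            if z == 8 and atom.GetFormalCharge() <= 0:
                self.acceptors.append(i)
            elif (
                z == 7
                and atom.GetFormalCharge() <= 0
                and atom.GetTotalNumHs(includeNeighbors=True) == 0
                and atom.GetTotalValence() <= 3
            ):
                self.acceptors.append(i)
        # explicit hydrogens attached to each donor (for the angle test)
        self.donor_hydrogens = {
            i: [
                nb.GetIdx()
                for nb in mol.GetAtomWithIdx(i).GetNeighbors()
                if nb.GetAtomicNum() == 1
            ]
            for i in self.donors
        }
        # charged groups: pattern groups first, then leftover formal charges
        self.charged_groups: list[tuple[int, frozenset[int]]] = []
        grouped: set[int] = set()
        for patt, sign in _ligand_charge_patterns:
            if patt is None:
                continue
            for m in mol.GetSubstructMatches(patt):
                ms = frozenset(m)
                self.charged_groups.append((sign, ms))
                grouped |= ms
        for i in self.heavy:
            atom = mol.GetAtomWithIdx(i)
            q = atom.GetFormalCharge()
            if q != 0 and i not in grouped:
                # skip the internal charges of neutral nitro groups
                if atom.GetAtomicNum() == 7 and q > 0 and any(
                    nb.GetAtomicNum() == 8 and nb.GetFormalCharge() < 0
                    for nb in atom.GetNeighbors()
                ):
                    continue
                if atom.GetAtomicNum() == 8 and q < 0 and any(
                    nb.GetAtomicNum() == 7 and nb.GetFormalCharge() > 0
                    for nb in atom.GetNeighbors()
                ):
                    continue
                self.charged_groups.append((int(np.sign(q)), frozenset([i])))


def _pocket_chemistry(pocket: PocketDefinition) -> list[_ResidueChemistry]:
    # memoized on the pocket instance (residue roles never change after build)
    chem = getattr(pocket, "_chemistry_cache", None)
    if chem is None:
        chem = [_ResidueChemistry(r) for r in pocket.residues]
        pocket._chemistry_cache = chem
    return chem


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosv = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def detect_interactions(
    pose: DockedPose,
    pocket: PocketDefinition,
    rules: InteractionRules | None = None,
    label_moieties: bool = True,
) -> list[InteractionRecord]:
    """All (residue, type) contacts of one pose with the pocket.

    Returns at most one record per (residue, itype); ``ligand_atoms``
    is the union of ligand heavy atoms involved and ``contact_point``
    the midpoint of the closest contributing atom pair.
    """
    rules = rules or InteractionRules()
    if len(pocket) == 0:
        return []
    lig = _LigandChemistry(pose)
    records: list[InteractionRecord] = []

    for rc in _pocket_chemistry(pocket):
        if rc.coords.shape[0] == 0:
            continue
        dmat = cdist(lig.coords, rc.coords)  # heavy x heavy
        lig_pos = {a: k for k, a in enumerate(lig.heavy)}
        # contributions[itype] -> list of (lig_atom, res_atom_idx, dist)
        contributions: dict[str, list[tuple[int, int, float]]] = {t: [] for t in ITYPES}
        excluded_pairs: set[tuple[int, int]] = set()

        # hydrogen bonds: ligand donor -> residue acceptor
        for d in lig.donors:
            for j in rc.acceptor_idx:
                dist = dmat[lig_pos[d], j]
                if dist > rules.hbond_distance:
                    continue
                hs = lig.donor_hydrogens.get(d, [])
                if hs:
                    ok = any(
                        _angle_deg(
                            lig.coords_all[d], lig.coords_all[h], rc.coords[j]
                        )
                        >= rules.hbond_angle
                        for h in hs
                    )
                    if not ok:
                        continue
                contributions["H"].append((d, j, dist))
                excluded_pairs.add((d, j))
        # hydrogen bonds: residue donor -> ligand acceptor (distance-only:
        # pocket residues carry heavy atoms only)
        for a in lig.acceptors:
            for j in rc.donor_idx:
                dist = dmat[lig_pos[a], j]
                if dist <= rules.hbond_distance:
                    contributions["H"].append((a, j, dist))
                    excluded_pairs.add((a, j))

        # electrostatics: opposite charged groups, closest-pair distance
        if rc.charge_sign != 0 and rc.charged_idx:
            for sign, group in lig.charged_groups:
                if sign * rc.charge_sign >= 0:
                    continue
                gl = [lig_pos[i] for i in group if i in lig_pos]
                if not gl:
                    continue
                sub = dmat[np.ix_(gl, rc.charged_idx)]
                if sub.min() <= rules.electrostatic_distance:
                    for gi, i in zip(gl, [x for x in group if x in lig_pos]):
                        for cj, j in enumerate(rc.charged_idx):
                            d_ = dmat[gi, j]
                            if d_ <= rules.electrostatic_distance:
                                contributions["E"].append((i, j, d_))
                                excluded_pairs.add((i, j))

        # van der Waals: remaining heavy-atom pairs within r_i + r_j + slack
        cut = np.minimum(
            lig.radii[:, None] + rc.radii[None, :] + rules.vdw_slack, rules.vdw_cap
        )
        ii, jj = np.nonzero(dmat <= cut)
        for k in range(len(ii)):
            i_mol = lig.heavy[ii[k]]
            if (i_mol, int(jj[k])) in excluded_pairs:
                continue
            contributions["V"].append((i_mol, int(jj[k]), float(dmat[ii[k], jj[k]])))

        for itype in ITYPES:
            contribs = contributions[itype]
            if not contribs:
                continue
            lig_atoms = tuple(sorted({c[0] for c in contribs}))
            best = min(contribs, key=lambda c: c[2])
            mid = 0.5 * (lig.coords_all[best[0]] + rc.coords[best[1]])
            label = (
                label_fragment(pose.mol, lig_atoms) if label_moieties else "unlabeled"
            )
            records.append(
                InteractionRecord(
                    compound_id=pose.compound_id,
                    residue=rc.ref,
                    itype=itype,
                    ligand_atoms=lig_atoms,
                    moiety_label=label,
                    contact_point=tuple(float(v) for v in mid),
                )
            )
    return records


def summarize_pose(records: Sequence[InteractionRecord]) -> dict[tuple[str, str], int]:
    """Binary flag per (residue key, itype): 1 iff >=1 record exists."""
    ids = {r.compound_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records mix compound_ids: {sorted(ids)}")
    flags: dict[tuple[str, str], int] = {}
    for r in records:
        flags[(r.residue.key, r.itype)] = 1
    return flags


# -- I/O -----------------------------------------------------------------------


def read_poses(
    sdf_path: str | Path, scores: dict[str, float] | None = None
) -> list[DockedPose]:
    """Read docked poses from an SDF file (one pose per compound).

    Compound ids come from the molecule title (``_Name``); docking
    scores from the ``scores`` mapping if given, else from an SDF
    property ``docking_score``, else 0.
    """
    supplier = Chem.SDMolSupplier(str(sdf_path), removeHs=False, sanitize=True)
    poses = []
    seen: set[str] = set()
    for k, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{sdf_path}: molecule #{k + 1} failed to parse")
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{k + 1}"
        if cid in seen:
            raise ValueError(f"{sdf_path}: duplicate compound_id {cid!r}")
        seen.add(cid)
        if scores is not None and cid in scores:
            e = scores[cid]
        elif mol.HasProp("docking_score"):
            e = float(mol.GetProp("docking_score"))
        else:
            e = 0.0
        poses.append(DockedPose(compound_id=cid, mol=mol, docking_score=e))
    return poses


def read_scores(path: str | Path) -> dict[str, float]:
    """2-column delimited table (compound_id, docking_score); TSV or CSV."""
    text = Path(path).read_text().strip().splitlines()
    delim = "\t" if "\t" in text[0] else ","
    out: dict[str, float] = {}
    for row in csv.reader(text, delimiter=delim):
        if not row or row[0].lower() in {"compound_id", "id"}:
            continue
        out[row[0]] = float(row[1])
    return out


def write_poses(poses: Iterable[DockedPose], sdf_path: str | Path) -> None:
    writer = Chem.SDWriter(str(sdf_path))
    writer.SetKekulize(True)
    for p in poses:
        p.mol.SetProp("_Name", p.compound_id)
        p.mol.SetProp("docking_score", repr(p.docking_score))
        writer.write(p.mol)
    writer.close()


def write_scores(scores: dict[str, float], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["compound_id", "docking_score"])
        for cid in sorted(scores):
            w.writerow([cid, repr(scores[cid])])
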