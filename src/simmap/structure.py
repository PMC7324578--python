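"""Protein structure input and catalytic-site (pocket) definition.

A binding site is defined the way most structure-based screening studies
define it: every residue with at least one heavy atom within a fixed
cutoff (default 8.0 A, boundary inclusive) of a bound reference ligand.
Hydrogens are ignored for the distance test because crystal structures
usually lack them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "ResidueRef",
    "Residue",
    "ProteinStructure",
    "PocketDefinition",
    "load_structure",
    "define_catalytic_site",
    "write_pdb",
]

_HYDROGEN = {"H", "D"}


@dataclass(frozen=True, order=True)
class ResidueRef:
    """Identity of a residue: (chain, number, insertion code) is unique."""

    chain_id: str
    residue_number: int
    residue_name: str
    insertion_code: str = ""

    @property
    def key(self) -> str:
        icode = self.insertion_code or ""
        return f"{self.chain_id}:{self.residue_number}{icode}"

    def __str__(self) -> str:  # e.g. "A:HIS368"
        return f"{self.chain_id}:{self.residue_name}{self.residue_number}{self.insertion_code}"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN


@dataclass
class Residue:
    ref: ResidueRef
    atoms: list[Atom] = field(default_factory=list)

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coord for a in self.atoms if a.is_heavy]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not found in {self.ref}")


class ProteinStructure:
    """Ordered polymer residues plus HETATM groups retrievable by name.

    Waters are dropped on load; other het groups (ligands, ions) are kept
    aside so that a reference ligand can be selected by residue name.
    """

    def __init__(self, residues: Sequence[Residue], het_groups: Sequence[Residue] = ()):
        if not residues:
            raise ValueError("structure contains no polymer residues")
        seen: set[tuple] = set()
        for r in residues:
            k = (r.ref.chain_id, r.ref.residue_number, r.ref.insertion_code)
            if k in seen:
                raise ValueError(f"duplicate residue identifier {r.ref}")
            seen.add(k)
            if not any(a.is_heavy for a in r.atoms):
                raise ValueError(f"residue {r.ref} has no heavy atom")
        self.residues: list[Residue] = list(residues)
        self.het_groups: list[Residue] = list(het_groups)

    def __len__(self) -> int:
        return len(self.residues)

    def het_by_name(self, resname: str, chain_id: str | None = None) -> list[Residue]:
        """All HETATM groups with the given residue name (e.g. a bound ligand)."""
        out = [
            g
            for g in self.het_groups
            if g.ref.residue_name == resname
            and (chain_id is None or g.ref.chain_id == chain_id)
        ]
        return out

    def ligand_coordinates(self, resname: str, chain_id: str | None = None) -> np.ndarray:
        """Heavy-atom coordinates of the named het group(s)."""
        groups = self.het_by_name(resname, chain_id)
        if not groups:
            raise ValueError(f"no HETATM group named {resname!r} in structure")
        return np.vstack([g.heavy_coords() for g in groups])


@dataclass
class PocketDefinition:
    """Catalytic-site residues selected by the distance-to-ligand rule."""

    residues: list[Residue]
    reference_ligand_id: str = ""
    cutoff_angstrom: float = 8.0

    @property
    def refs(self) -> list[ResidueRef]:
        return [r.ref for r in self.residues]

    def __len__(self) -> int:
        return len(self.residues)

    def residue_by_key(self, key: str) -> Residue:
        for r in self.residues:
            if r.ref.key == key:
                return r
        raise KeyError(key)


_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per name: highest occupancy wins, then altloc order."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None or (atom.occ, -ord(atom.altloc or "A")) > (
            prev.occ,
            -ord(prev.altloc or "A"),
        ):
            by_name[atom.name] = atom
    # preserve file order of first appearance
    order: list[str] = []
    for atom in res:
        if atom.name not in order:
            order.append(atom.name)
    return [by_name[n] for n in order]


def _convert(res: gemmi.Residue, chain_id: str) -> Residue:
    ref = ResidueRef(
        chain_id=chain_id,
        residue_number=res.seqid.num,
        residue_name=res.name.strip(),
        insertion_code=(res.seqid.icode or "").strip(),
    )
    atoms = [
        Atom(name=a.name, element=a.element.name, coord=(a.pos.x, a.pos.y, a.pos.z))
        for a in _pick_altlocs(res)
    ]
    return Residue(ref=ref, atoms=atoms)


def load_structure(path: str | Path) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Standard (polymer) residues become the ordered residue list; HETATM
    groups other than water are kept for ligand selection. Alternate
    locations are collapsed to the highest-occupancy conformer.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: structure contains no models")
    model = st[0]
    residues: list[Residue] = []
    hets: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_polymer = info is not None and info.is_amino_acid()
            target = residues if (res.het_flag == "A" or is_polymer) else hets
            target.append(_convert(res, chain.name))
    if not residues:
        raise ValueError(f"{path}: no polymer (ATOM) residues found")
    return ProteinStructure(residues, hets)


def define_catalytic_site(
    structure: ProteinStructure,
    ligand_atoms: np.ndarray,
    cutoff: float = 8.0,
    reference_ligand_id: str = "",
) -> PocketDefinition:
    """Residues with any heavy atom within ``cutoff`` of any ligand heavy atom.

    The boundary is inclusive; ordering follows the structure. An empty
    pocket is returned with a warning rather than an error.
    """
    ligand_atoms = np.asarray(ligand_atoms, dtype=float).reshape(-1, 3)
    if ligand_atoms.shape[0] == 0:
        raise ValueError("reference ligand has no heavy atoms")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    selected: list[Residue] = []
    for res in structure.residues:
        pts = res.heavy_coords()
        if pts.shape[0] and cdist(pts, ligand_atoms).min() <= cutoff:
            selected.append(res)
    if not selected:
        warnings.warn(
            f"no residue within {cutoff} A of the reference ligand: empty pocket",
            stacklevel=2,
        )
    return PocketDefinition(
        residues=selected,
        reference_ligand_id=reference_ligand_id,
        cutoff_angstrom=cutoff,
    )


def write_pdb(
    structure: ProteinStructure,
    path: str | Path,
    ligand: Residue | None = None,
) -> None:
    """Write the structure (and optionally one het group) as a PDB file."""
    st = gemmi.Structure()
    st.name = "simmap"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def add(res: Residue, het: bool) -> None:
        ch = chains.setdefault(res.ref.chain_id, gemmi.Chain(res.ref.chain_id))
        g = gemmi.Residue()
        g.name = res.ref.residue_name
        g.seqid = gemmi.SeqId(res.ref.residue_number, res.ref.insertion_code or " ")
        g.het_flag = "H" if het else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coord)
            ga.occ = 1.0
            g.add_atom(ga)
        ch.add_residue(g)

    for res in structure.residues:
        add(res, het=False)
    if ligand is not None:
        add(ligand, het=True)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
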