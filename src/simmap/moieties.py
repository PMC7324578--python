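"""Functional-group (moiety) detection and the 90-bit moiety fingerprint.

The catalog is an ordered, versioned table of 90 SMARTS patterns in the
spirit of checkmol's functional-group classification. Bit k of a
fingerprint is set iff group k matches at least once. Interaction
records reuse the same catalog to label the ligand fragment at a
contact point.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from rdkit import Chem

__all__ = [
    "MoietyCatalog",
    "MoietyFingerprint",
    "load_catalog",
    "detect_moieties",
    "fingerprint",
    "label_fragment",
]

N_BITS = 90


@dataclass(frozen=True)
class MoietyFingerprint:
    compound_id: str
    bits: tuple[int, ...]
    catalog_version: str

    def __post_init__(self) -> None:
        if len(self.bits) != N_BITS:
            raise ValueError(f"fingerprint must have {N_BITS} bits, got {len(self.bits)}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.uint8)

    @property
    def group_names(self) -> tuple[str, ...]:
        cat = load_catalog()
        return tuple(n for n, b in zip(cat.names, self.bits) if b)


class MoietyCatalog:
    """Ordered (group_name, SMARTS) table; order is the bit order."""

    def __init__(self, version: str, groups: Sequence[tuple[str, str]]):
        self.version = version
        self.names: list[str] = []
        self.patterns: list[Chem.Mol] = []
        seen: set[str] = set()
        for name, smarts in groups:
            if name in seen:
                raise ValueError(f"duplicate group name {name!r}")
            seen.add(name)
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"group {name!r}: invalid SMARTS {smarts!r}")
            self.names.append(name)
            self.patterns.append(patt)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@functools.lru_cache(maxsize=4)
def load_catalog(path: str | None = None) -> MoietyCatalog:
    """Load the shipped catalog (or a user-supplied YAML of the same shape)."""
    if path is None:
        text = (resources.files("simmap") / "data" / "moiety_catalog_v1.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    cat = MoietyCatalog(doc["version"], [(g["name"], g["smarts"]) for g in doc["groups"]])
    if path is None and len(cat) != N_BITS:
        raise ValueError(f"shipped catalog must define {N_BITS} groups, found {len(cat)}")
    return cat


def _require_mol(mol: Chem.Mol, compound_id: str = "") -> Chem.Mol:
    if mol is None:
        raise ValueError(f"unparseable molecule {compound_id!r}")
    return mol


def detect_moieties(mol: Chem.Mol, catalog: MoietyCatalog | None = None) -> set[str]:
    """Names of all catalog groups present (>=1 substructure match)."""
    catalog = catalog or load_catalog()
    _require_mol(mol)
    out: set[str] = set()
    for name, patt in zip(catalog.names, catalog.patterns):
        if mol.HasSubstructMatch(patt):
            out.add(name)
    return out


def fingerprint(
    mol: Chem.Mol, compound_id: str = "", catalog: MoietyCatalog | None = None
) -> MoietyFingerprint:
    """90-bit presence/absence fingerprint, bit order fixed by the catalog."""
    catalog = catalog or load_catalog()
    _require_mol(mol, compound_id)
    bits = tuple(
        int(mol.HasSubstructMatch(patt)) for patt in catalog.patterns
    )
    return MoietyFingerprint(compound_id=compound_id, bits=bits, catalog_version=catalog.version)


def fingerprints_to_frame(fps: Iterable[MoietyFingerprint]):
    """Compound x 90-bit table (pandas DataFrame, columns = group names)."""
    import pandas as pd

    fps = list(fps)
    cat = load_catalog()
    return pd.DataFrame(
        [fp.bits for fp in fps],
        index=[fp.compound_id for fp in fps],
        columns=cat.names,
    )


# -- fragment labeling for interaction records --------------------------------

_label_cache: dict[tuple, str] = {}


def label_fragment(
    mol: Chem.Mol,
    contact_atoms: Sequence[int],
    catalog: MoietyCatalog | None = None,
) -> str:
    """Moiety label for the ligand fragment around a protein contact.

    The fragment is the contact atoms plus their one-bond neighbours
    (heavy atoms). Among catalog groups with at least one match, the
    label is the group whose matched atom set best covers the fragment;
    ties go to the smaller match, then to the group with fewer matches
    in the whole molecule (more specific), then alphabetically.
    Returns ``"unclassified"`` when nothing in the catalog matches.
    """
    catalog = catalog or load_catalog()
    frag: set[int] = set(int(i) for i in contact_atoms)
    for idx in list(frag):
        for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
            if nb.GetAtomicNum() > 1:
                frag.add(nb.GetIdx())

    key = (id(catalog), Chem.MolToSmiles(mol), tuple(sorted(
        Chem.CanonicalRankAtoms(mol)[i] for i in frag)))
    cached = _label_cache.get(key)
    if cached is not None:
        return cached

    best: tuple | None = None
    best_name = "unclassified"
    for name, patt in zip(catalog.names, catalog.patterns):
        matches = mol.GetSubstructMatches(patt)
        if not matches:
            continue
        for m in matches:
            mset = set(m)
            overlap = len(mset & frag)
            if overlap == 0:
                continue
            score = (-overlap, len(mset), len(matches), name)
            if best is None or score < best:
                best = score
                best_name = name
    if len(_label_cache) < 100_000:
        _label_cache[key] = best_name
    return best_name
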