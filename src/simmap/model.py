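"""Model/Results surface for building and using a site-moiety map.

:class:`SiteMoietyModel` holds the inputs (protein, reference ligand,
docked poses, docking scores) and configuration; :meth:`fit` runs the
pipeline — pocket definition, interaction detection, profile matrices,
shuffle-null Z-scores, anchor grouping, moiety preferences — and
returns a :class:`SiteMoietyMapResults` carrying the map, the
per-residue statistics, a text ``summary()``, compound scoring, and
JSON (de)serialization.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .interactions import (
    DockedPose,
    InteractionRecord,
    InteractionRules,
    ITYPES,
    detect_interactions,
)
from .profiles import (
    Anchor,
    InteractionProfile,
    ResidueStatistic,
    SiteMoietyMap,
    build_profiles,
    group_anchors,
    moiety_preferences,
    residue_zscores,
    select_top_compounds,
)
from .scoring import rank_compounds, score_compound
from .structure import (
    Atom,
    PocketDefinition,
    ProteinStructure,
    Residue,
    ResidueRef,
    define_catalytic_site,
)

__all__ = ["SimmapConfig", "SiteMoietyModel", "SiteMoietyMapResults", "build_simmap"]


@dataclass
class SimmapConfig:
    """All tunables; defaults follow the published protocol (8 A pocket,
    top 2,000 compounds, 1,000 shuffles, one-sided Z >= 1.645)."""

    cutoff_angstrom: float = 8.0
    top_k: int = 2000
    n_shuffles: int = 1000
    z_threshold: float = 1.645
    link_distance: float = 3.5
    seed: int = 0
    rules: InteractionRules = field(default_factory=InteractionRules)

    def __post_init__(self) -> None:
        if self.cutoff_angstrom <= 0 or self.top_k < 1 or self.n_shuffles < 1:
            raise ValueError("invalid configuration value")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimmapConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        rules = InteractionRules(**doc.pop("rules", {}))
        return cls(rules=rules, **doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


class SiteMoietyModel:
    """Site-moiety map model over a pocket and an ensemble of docked poses."""

    def __init__(
        self,
        structure: ProteinStructure,
        ligand_coords: np.ndarray,
        poses: Sequence[DockedPose],
        scores: Mapping[str, float] | None = None,
        config: SimmapConfig | None = None,
        reference_ligand_id: str = "",
    ):
        if not poses:
            raise ValueError("no docked poses supplied")
        self.structure = structure
        self.ligand_coords = np.asarray(ligand_coords, dtype=float).reshape(-1, 3)
        self.poses = {p.compound_id: p for p in poses}
        if len(self.poses) != len(poses):
            raise ValueError("duplicate compound_id among poses")
        self.scores = (
            dict(scores)
            if scores is not None
            else {p.compound_id: p.docking_score for p in poses}
        )
        missing = set(self.poses) - set(self.scores)
        if missing:
            raise ValueError(f"poses without docking scores: {sorted(missing)[:5]}")
        self.config = config or SimmapConfig()
        self.reference_ligand_id = reference_ligand_id

    @classmethod
    def from_files(
        cls,
        protein_pdb: str | Path,
        poses_sdf: str | Path,
        scores_path: str | Path | None = None,
        ligand_resname: str = "",
        ligand_chain: str | None = None,
        ligand_pdb: str | Path | None = None,
        config: SimmapConfig | None = None,
    ) -> "SiteMoietyModel":
        from .interactions import read_poses, read_scores
        from .structure import load_structure

        structure = load_structure(protein_pdb)
        if ligand_pdb is not None:
            lig_structure = load_structure(ligand_pdb)
            coords = np.vstack(
                [r.heavy_coords() for r in lig_structure.het_groups]
                or [r.heavy_coords() for r in lig_structure.residues]
            )
            ref_id = str(ligand_pdb)
        else:
            if not ligand_resname:
                raise ValueError("give ligand_resname or ligand_pdb")
            coords = structure.ligand_coordinates(ligand_resname, ligand_chain)
            ref_id = ligand_resname
        scores = read_scores(scores_path) if scores_path else None
        poses = read_poses(poses_sdf, scores)
        return cls(structure, coords, poses, scores, config, reference_ligand_id=ref_id)

    def fit(self, seed: int | None = None) -> "SiteMoietyMapResults":
        """Run the full pipeline and return the fitted map."""
        cfg = self.config
        master_seed = cfg.seed if seed is None else seed
        pocket = define_catalytic_site(
            self.structure,
            self.ligand_coords,
            cfg.cutoff_angstrom,
            reference_ligand_id=self.reference_ligand_id,
        )
        top_ids = select_top_compounds(self.scores, cfg.top_k)
        top_ids = [cid for cid in top_ids if cid in self.poses]
        records_by_compound = {
            cid: detect_interactions(self.poses[cid], pocket, cfg.rules)
            for cid in top_ids
        }
        profiles = build_profiles(records_by_compound, pocket.refs)
        # one child seed per interaction type, derived from the master seed
        children = np.random.SeedSequence(master_seed).spawn(len(ITYPES))
        stats_by_type: dict[str, list[ResidueStatistic]] = {}
        for itype, child in zip(ITYPES, children):
            stats_by_type[itype] = residue_zscores(
                profiles[itype],
                n_shuffles=cfg.n_shuffles,
                z_threshold=cfg.z_threshold,
                seed=np.random.default_rng(child),
            )
        all_records = [r for recs in records_by_compound.values() for r in recs]
        anchors = group_anchors(
            stats_by_type, all_records, cfg.link_distance, pocket_order=pocket.refs
        )
        for anchor in anchors:
            anchor.moiety_preferences = moiety_preferences(anchor, all_records, top_ids)
        provenance = {
            "n_compounds_docked": len(self.poses),
            "n_top_used": len(top_ids),
            "shuffle_count": cfg.n_shuffles,
            "z_threshold": cfg.z_threshold,
            "rng_seed": master_seed,
            "cutoff_angstrom": cfg.cutoff_angstrom,
            "link_distance": cfg.link_distance,
            "config_digest": self.config.digest(),
            "package_version": _pkg_version,
        }
        simmap = SiteMoietyMap(anchors=anchors, pocket=pocket, provenance=provenance)
        return SiteMoietyMapResults(
            map=simmap,
            profiles=profiles,
            stats_by_type=stats_by_type,
            records_by_compound=records_by_compound,
            config=cfg,
        )


@dataclass
class SiteMoietyMapResults:
    """Fitted site-moiety map plus the statistics behind it."""

    map: SiteMoietyMap
    profiles: dict[str, InteractionProfile]
    stats_by_type: dict[str, list[ResidueStatistic]]
    records_by_compound: dict[str, list[InteractionRecord]]
    config: SimmapConfig

    # -- inspection -----------------------------------------------------------

    @property
    def anchors(self) -> list[Anchor]:
        return self.map.anchors

    def residue_stats(self) -> pd.DataFrame:
        rows = []
        for itype, stats in self.stats_by_type.items():
            for s in stats:
                rows.append(
                    {
                        "residue": str(s.residue),
                        "itype": itype,
                        "frequency": s.frequency,
                        "null_mean": s.null_mean,
                        "null_sd": s.null_sd,
                        "zscore": s.zscore,
                        "significant": s.significant,
                        "degenerate": s.degenerate,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        prov = self.map.provenance
        lines = [
            "Site-moiety map",
            "=" * 60,
            f"pocket residues: {len(self.map.pocket)}  "
            f"(cutoff {prov['cutoff_angstrom']} A)",
            f"compounds: {prov['n_top_used']} used of {prov['n_compounds_docked']} docked",
            f"shuffles: {prov['shuffle_count']}   Z threshold: {prov['z_threshold']}",
            f"anchors: {len(self.anchors)}",
            "-" * 60,
        ]
        for a in self.anchors:
            res = ", ".join(str(r) for r in a.residues)
            lines.append(f"{a.anchor_id:>4} [{a.itype}]  residues: {res}")
            for m, f in a.moiety_preferences[:3]:
                lines.append(f"        {m:<24} {f:6.1%}")
        return "\n".join(lines)

    # -- scoring --------------------------------------------------------------

    def score_compounds(
        self,
        poses: Sequence[DockedPose],
        scores: Mapping[str, float] | None = None,
    ) -> pd.DataFrame:
        """SiMMap-score a compound library against the fitted anchors.

        Returns a ranked table: rank, compound_id, simmap_score, one
        AS column per anchor, docking_score and heavy-atom count.
        """
        scores = scores or {p.compound_id: p.docking_score for p in poses}
        compound_scores = []
        for pose in poses:
            records = detect_interactions(
                pose, self.map.pocket, self.config.rules, label_moieties=False
            )
            compound_scores.append(
                score_compound(
                    pose.compound_id,
                    records,
                    self.anchors,
                    scores[pose.compound_id],
                    pose.heavy_atom_count,
                )
            )
        ranked = rank_compounds(compound_scores)
        rows = []
        for s in ranked:
            row = {
                "rank": s.rank,
                "compound_id": s.compound_id,
                "simmap_score": s.simmap_score,
            }
            row.update({f"AS_{aid}": v for aid, v in s.anchor_scores.items()})
            row["docking_score"] = s.docking_score
            row["atom_count"] = s.atom_count
            rows.append(row)
        return pd.DataFrame(rows)

    # -- serialization --------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = self.map.to_dict()
        doc["pocket"]["atoms"] = {
            r.ref.key: {
                "residue_name": r.ref.residue_name,
                "chain_id": r.ref.chain_id,
                "residue_number": r.ref.residue_number,
                "insertion_code": r.ref.insertion_code,
                "atoms": [
                    [a.name, a.element, [round(v, 4) for v in a.coord]]
                    for a in r.atoms
                ],
            }
            for r in self.map.pocket.residues
        }
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def export_profiles(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for itype, profile in self.profiles.items():
            pd.DataFrame(
                profile.matrix,
                index=profile.compound_ids,
                columns=[str(r) for r in profile.residues],
            ).to_csv(directory / f"profile_{itype}.csv")

    def export_pymol_dump(self, path: str | Path) -> None:
        """Anchor centroids and member residues as a plain-data CSV."""
        rows = []
        for a in self.anchors:
            rows.append(
                {
                    "anchor_id": a.anchor_id,
                    "itype": a.itype,
                    "x": a.centroid[0],
                    "y": a.centroid[1],
                    "z": a.centroid[2],
                    "residues": ";".join(str(r) for r in a.residues),
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)


def load_map_json(path: str | Path) -> SiteMoietyMap:
    """Reload a serialized map (with pocket geometry) for later scoring."""
    doc = json.loads(Path(path).read_text())
    residues = []
    refs_by_key: dict[str, ResidueRef] = {}
    for key, rd in doc["pocket"]["atoms"].items():
        ref = ResidueRef(
            chain_id=rd["chain_id"],
            residue_number=rd["residue_number"],
            residue_name=rd["residue_name"],
            insertion_code=rd.get("insertion_code", ""),
        )
        refs_by_key[key] = ref
        residues.append(
            Residue(
                ref=ref,
                atoms=[Atom(n, e, tuple(c)) for n, e, c in rd["atoms"]],
            )
        )
    order = {k: i for i, k in enumerate(doc["pocket"]["residues"])}
    residues.sort(key=lambda r: order.get(r.ref.key, 10**6))
    pocket = PocketDefinition(
        residues=residues,
        reference_ligand_id=doc["pocket"].get("reference_ligand_id", ""),
        cutoff_angstrom=doc["pocket"].get("cutoff_angstrom", 8.0),
    )

    def _ref_from_str(s: str) -> ResidueRef:
        # anchors store "chain:NAMEnumber[icode]" strings; match via pocket keys
        for key, ref in refs_by_key.items():
            if str(ref) == s:
                return ref
        raise KeyError(f"anchor residue {s!r} not in pocket")

    anchors = []
    for ad in doc["anchors"]:
        anchors.append(
            Anchor(
                anchor_id=ad["anchor_id"],
                itype=ad["itype"],
                residues=[_ref_from_str(s) for s in ad["residues"]],
                centroid=tuple(ad["centroid"]),
                moiety_preferences=[
                    (m["moiety"], m["frequency"]) for m in ad["moiety_preferences"]
                ],
                type_residues={
                    t: [_ref_from_str(s) for s in rs]
                    for t, rs in ad.get("type_residues", {}).items()
                },
            )
        )
    return SiteMoietyMap(anchors=anchors, pocket=pocket, provenance=doc["provenance"])


def build_simmap(
    structure: ProteinStructure,
    ligand_coords: np.ndarray,
    poses: Sequence[DockedPose],
    scores: Mapping[str, float] | None = None,
    config: SimmapConfig | None = None,
) -> SiteMoietyMapResults:
    """One-call pipeline: construct the model and fit it."""
    return SiteMoietyModel(structure, ligand_coords, poses, scores, config).fit()
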