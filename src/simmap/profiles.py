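"""Interaction profiles, shuffle-null consensus residues, and anchors.

For each interaction type I in {E, H, V} an N x R binary profile M(I)
records whether compound i contacts residue r with that type. Consensus
residues are found against a permutation null: every shuffle permutes
each row independently (preserving each compound's contact count), the
per-column interaction frequency is recomputed, and the observed
frequency f_j is standardised by the null mean and standard deviation,

    Z_j = (f_j - mu_j) / sigma_j ,

with Z_j >= 1.645 (one-sided 95%) declared significant. Significant
residues of one type are grouped spatially into anchors; an
electrostatic and a hydrogen-bond anchor that coincide become a
combined EH anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .interactions import ITYPES, InteractionRecord
from .structure import PocketDefinition, ResidueRef

__all__ = [
    "InteractionProfile",
    "ResidueStatistic",
    "Anchor",
    "SiteMoietyMap",
    "build_profiles",
    "select_top_compounds",
    "residue_zscores",
    "group_anchors",
    "moiety_preferences",
]

Z_THRESHOLD_95 = 1.645  # one-sided 95% normal quantile
DEFAULT_SHUFFLES = 1000
DEFAULT_LINK_DISTANCE = 3.5


@dataclass
class InteractionProfile:
    itype: str
    matrix: np.ndarray  # N x R, uint8
    compound_ids: list[str]
    residues: list[ResidueRef]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        n, r = self.matrix.shape
        if n != len(self.compound_ids) or r != len(self.residues):
            raise ValueError("profile dimensions do not match labels")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("profile entries must be binary")

    @property
    def frequencies(self) -> np.ndarray:
        """Per-residue interaction frequency f_j (column mean)."""
        return self.matrix.mean(axis=0)


@dataclass(frozen=True)
class ResidueStatistic:
    residue: ResidueRef
    itype: str
    frequency: float
    null_mean: float
    null_sd: float
    zscore: float
    significant: bool
    degenerate: bool = False  # sigma = 0 fallback applied


@dataclass
class Anchor:
    """A consensus pocket: spatially grouped significant residues.

    ``itype`` is E, H, V, or EH for a merged electrostatic/hydrogen
    anchor; ``type_residues`` records which member residues were
    significant for which type.
    """

    anchor_id: str
    itype: str
    residues: list[ResidueRef]
    centroid: tuple[float, float, float]
    moiety_preferences: list[tuple[str, float]] = field(default_factory=list)
    type_residues: dict[str, list[ResidueRef]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "anchor_id": self.anchor_id,
            "itype": self.itype,
            "residues": [str(r) for r in self.residues],
            "centroid": [round(v, 4) for v in self.centroid],
            "moiety_preferences": [
                {"moiety": m, "frequency": round(f, 6)}
                for m, f in self.moiety_preferences
            ],
            "type_residues": {
                t: [str(r) for r in rs] for t, rs in sorted(self.type_residues.items())
            },
        }


@dataclass
class SiteMoietyMap:
    anchors: list[Anchor]
    pocket: PocketDefinition
    provenance: dict

    def anchor_by_id(self, anchor_id: str) -> Anchor:
        for a in self.anchors:
            if a.anchor_id == anchor_id:
                return a
        raise KeyError(anchor_id)

    def to_dict(self) -> dict:
        return {
            "anchors": [a.to_dict() for a in self.anchors],
            "pocket": {
                "residues": [str(r) for r in self.pocket.refs],
                "reference_ligand_id": self.pocket.reference_ligand_id,
                "cutoff_angstrom": self.pocket.cutoff_angstrom,
            },
            "provenance": self.provenance,
        }


def select_top_compounds(scores: Mapping[str, float], k: int = 2000) -> list[str]:
    """The k best (lowest docking energy) compounds; ties by compound id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(scores, key=lambda c: (scores[c], c))
    if k > len(ordered):
        warnings.warn(
            f"requested top {k} but only {len(ordered)} compounds available",
            stacklevel=2,
        )
    return ordered[:k]


def build_profiles(
    records_by_compound: Mapping[str, Sequence[InteractionRecord]],
    residues: Sequence[ResidueRef],
) -> dict[str, InteractionProfile]:
    """Three N x R binary profiles (E, H, V) from per-compound records."""
    compound_ids = list(records_by_compound)
    if len(set(compound_ids)) != len(compound_ids):
        raise ValueError("duplicate compound_id")
    if not compound_ids or not residues:
        raise ValueError("need >=1 compound and >=1 residue")
    res_index = {r.key: j for j, r in enumerate(residues)}
    mats = {t: np.zeros((len(compound_ids), len(residues)), dtype=np.uint8) for t in ITYPES}
    for i, cid in enumerate(compound_ids):
        for rec in records_by_compound[cid]:
            j = res_index.get(rec.residue.key)
            if j is not None:
                mats[rec.itype][i, j] = 1
    return {
        t: InteractionProfile(t, mats[t], list(compound_ids), list(residues))
        for t in ITYPES
    }


def _shuffled_frequencies(
    m: np.ndarray, n_shuffles: int, rng: np.random.Generator, chunk: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Null mean and population SD of column frequencies under row shuffles."""
    n, r = m.shape
    s1 = np.zeros(r)
    s2 = np.zeros(r)
    done = 0
    while done < n_shuffles:
        b = min(chunk, n_shuffles - done)
        # independent permutation of each row: argsort of uniform keys
        perm = np.argsort(rng.random((b, n, r)), axis=2)
        shuffled = np.take_along_axis(np.broadcast_to(m, (b, n, r)), perm, axis=2)
        freq = shuffled.mean(axis=1)  # b x r
        s1 += freq.sum(axis=0)
        s2 += (freq**2).sum(axis=0)
        done += b
    mu = s1 / n_shuffles
    var = np.maximum(s2 / n_shuffles - mu**2, 0.0)
    return mu, np.sqrt(var)


def residue_zscores(
    profile: InteractionProfile,
    n_shuffles: int = DEFAULT_SHUFFLES,
    z_threshold: float = Z_THRESHOLD_95,
    seed: int | np.random.Generator = 0,
) -> list[ResidueStatistic]:
    """Consensus statistics per residue from the within-row shuffle null.

    sigma is the population standard deviation over shuffle replicates.
    If sigma_j = 0 (permutation-invariant column, e.g. all-ones rows or
    R = 1), Z_j is +inf when f_j > mu_j and 0 otherwise, flagged as
    degenerate.
    """
    m = profile.matrix
    if m.shape[0] < 2:
        raise ValueError("need N >= 2 compounds for the shuffle null")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = profile.frequencies
    mu, sd = _shuffled_frequencies(m, n_shuffles, rng)
    sd[sd <= 1e-7] = 0.0  # guard against cancellation noise in the variance
    stats = []
    for j, res in enumerate(profile.residues):
        if sd[j] > 0:
            z = float((f[j] - mu[j]) / sd[j])
            degenerate = False
        else:
            z = float("inf") if f[j] > mu[j] + 1e-9 else 0.0
            degenerate = True
        stats.append(
            ResidueStatistic(
                residue=res,
                itype=profile.itype,
                frequency=float(f[j]),
                null_mean=float(mu[j]),
                null_sd=float(sd[j]),
                zscore=z,
                significant=bool(z >= z_threshold),
                degenerate=degenerate,
            )
        )
    return stats


def _mean_contact_points(
    records: Iterable[InteractionRecord],
) -> dict[tuple[str, str], np.ndarray]:
    """Mean contact point per (residue key, itype)."""
    sums: dict[tuple[str, str], np.ndarray] = {}
    counts: dict[tuple[str, str], int] = {}
    for r in records:
        k = (r.residue.key, r.itype)
        sums[k] = sums.get(k, np.zeros(3)) + np.asarray(r.contact_point)
        counts[k] = counts.get(k, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


def _cluster_points(points: np.ndarray, link_distance: float) -> np.ndarray:
    """Single-linkage clusters of 3D points; labels start at 1."""
    if points.shape[0] == 1:
        return np.array([1])
    z = linkage(points, method="single")
    return fcluster(z, t=link_distance, criterion="distance")


def group_anchors(
    stats_by_type: Mapping[str, Sequence[ResidueStatistic]],
    records: Sequence[InteractionRecord],
    link_distance: float = DEFAULT_LINK_DISTANCE,
    pocket_order: Sequence[ResidueRef] | None = None,
) -> list[Anchor]:
    """Group significant residues into typed anchors.

    Within each type, significant residues are single-linkage clustered
    on their mean contact points; each cluster becomes an anchor whose
    centroid is the mean of those points. An E anchor and an H anchor
    that share a residue or whose centroids lie within ``link_distance``
    merge into one EH anchor. Anchors are named by type plus rank of
    descending member count (ties by pocket order of the first member).
    """
    mean_points = _mean_contact_points(records)
    order_index = (
        {r.key: i for i, r in enumerate(pocket_order)} if pocket_order else {}
    )

    # raw clusters per type: list of (itype, [refs], centroid)
    raw: dict[str, list[dict]] = {t: [] for t in ITYPES}
    for itype, stats in stats_by_type.items():
        sig = [s for s in stats if s.significant]
        sig = [s for s in sig if (s.residue.key, itype) in mean_points]
        if not sig:
            continue
        pts = np.array([mean_points[(s.residue.key, itype)] for s in sig])
        labels = _cluster_points(pts, link_distance)
        for lab in sorted(set(labels)):
            idx = [i for i, l_ in enumerate(labels) if l_ == lab]
            members = [sig[i].residue for i in idx]
            centroid = pts[idx].mean(axis=0)
            raw[itype].append(
                {"itype": itype, "residues": members, "centroid": centroid}
            )

    # merge E/H cluster pairs into EH anchors
    merged: list[dict] = []
    used_e: set[int] = set()
    used_h: set[int] = set()
    for ie, ce in enumerate(raw["E"]):
        for ih, ch in enumerate(raw["H"]):
            if ih in used_h:
                continue
            share = {r.key for r in ce["residues"]} & {r.key for r in ch["residues"]}
            close = np.linalg.norm(ce["centroid"] - ch["centroid"]) <= link_distance
            if share or close:
                members: list[ResidueRef] = list(ce["residues"])
                for r in ch["residues"]:
                    if r.key not in {m.key for m in members}:
                        members.append(r)
                merged.append(
                    {
                        "itype": "EH",
                        "residues": members,
                        "centroid": 0.5 * (ce["centroid"] + ch["centroid"]),
                        "type_residues": {
                            "E": list(ce["residues"]),
                            "H": list(ch["residues"]),
                        },
                    }
                )
                used_e.add(ie)
                used_h.add(ih)
                break
    clusters = merged
    clusters += [c for i, c in enumerate(raw["E"]) if i not in used_e]
    clusters += [c for i, c in enumerate(raw["H"]) if i not in used_h]
    clusters += raw["V"]

    if not clusters:
        warnings.warn("no significant residues: empty anchor list", stacklevel=2)
        return []

    def pocket_rank(c: dict) -> int:
        return min(order_index.get(r.key, 10**6) for r in c["residues"])

    anchors: list[Anchor] = []
    by_type: dict[str, list[dict]] = {}
    for c in clusters:
        by_type.setdefault(c["itype"], []).append(c)
    for itype, group in by_type.items():
        group.sort(key=lambda c: (-len(c["residues"]), pocket_rank(c)))
        for rank, c in enumerate(group, start=1):
            anchors.append(
                Anchor(
                    anchor_id=f"{itype}{rank}",
                    itype=itype,
                    residues=list(c["residues"]),
                    centroid=tuple(float(v) for v in c["centroid"]),
                    type_residues=c.get(
                        "type_residues", {itype: list(c["residues"])}
                    ),
                )
            )
    type_order = {"EH": 0, "E": 1, "H": 2, "V": 3}
    anchors.sort(key=lambda a: (type_order.get(a.itype, 9), a.anchor_id))
    return anchors


def moiety_preferences(
    anchor: Anchor,
    records: Sequence[InteractionRecord],
    compound_ids: Sequence[str],
) -> list[tuple[str, float]]:
    """Ranked (moiety, frequency) preferences of an anchor.

    Frequency = fraction of profile compounds with at least one record
    of the anchor's type(s) at an anchor residue bearing that moiety;
    descending, ties alphabetical.
    """
    types = ("E", "H") if anchor.itype == "EH" else (anchor.itype,)
    anchor_keys = {r.key for r in anchor.residues}
    compounds_with: dict[str, set[str]] = {}
    for rec in records:
        if rec.itype in types and rec.residue.key in anchor_keys:
            compounds_with.setdefault(rec.moiety_label, set()).add(rec.compound_id)
    n = len(compound_ids)
    if n == 0:
        return []
    prefs = [
        (moiety, len(cids & set(compound_ids)) / n)
        for moiety, cids in compounds_with.items()
    ]
    prefs = [(m, f) for m, f in prefs if f > 0]
    prefs.sort(key=lambda mf: (-mf[1], mf[0]))
    return prefs
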