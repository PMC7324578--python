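"""Compound-similarity clustering and anchor conservation summaries.

Structural novelty of inhibitors is judged from their moiety
fingerprints: the pairwise distance is 1 - Pearson r between 90-bit
vectors, and compounds are grouped by hierarchical clustering with
centroid linkage. Centroid linkage needs coordinates, so the linkage
runs on the raw bit vectors; the Pearson distance matrix is emitted
alongside for heatmap ordering.

Anchor conservation averages user-supplied per-residue grades on the
ConSurf-style 1 (variable) to 9 (conserved) scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree

from .moieties import MoietyFingerprint
from .profiles import Anchor

__all__ = [
    "DistanceMatrix",
    "ClusterTree",
    "pearson_distance",
    "centroid_cluster",
    "cut_clusters",
    "novelty_report",
    "anchor_conservation",
    "read_conservation_table",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, values in [0, 2]


@dataclass
class ClusterTree:
    ids: list[str]
    merges: np.ndarray  # scipy linkage matrix, (n-1) x 4

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def inversions(self) -> int:
        """Centroid linkage allows non-monotone merge heights; count them."""
        h = self.merges[:, 2]
        return int(np.sum(np.diff(h) < 0))

    def to_newick(self) -> str:
        root = to_tree(self.merges)

        def walk(node) -> str:
            if node.is_leaf():
                return self.ids[node.id].replace(" ", "_")
            return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

        return walk(root) + ";"


def _bit_matrix(fps: Sequence[MoietyFingerprint]) -> tuple[list[str], np.ndarray]:
    ids = [fp.compound_id for fp in fps]
    x = np.array([fp.bits for fp in fps], dtype=float)
    return ids, x


def pearson_distance(fps: Sequence[MoietyFingerprint]) -> DistanceMatrix:
    """d_ij = 1 - Pearson r between fingerprint bit vectors."""
    if len(fps) < 2:
        raise ValueError("need >= 2 fingerprints")
    ids, x = _bit_matrix(fps)
    sd = x.std(axis=1)
    for cid, s in zip(ids, sd):
        if s == 0:
            raise ValueError(
                f"fingerprint of {cid!r} has zero variance (all bits equal); "
                "Pearson distance undefined"
            )
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, 2.0)
    return DistanceMatrix(ids=ids, d=d)


def centroid_cluster(fps: Sequence[MoietyFingerprint]) -> ClusterTree:
    """Centroid-linkage hierarchy on the raw bit vectors.

    Input is sorted by compound id first so that merge order is
    deterministic under reordering of the input (up to exact ties).
    """
    if len(fps) < 2:
        raise ValueError("need >= 2 fingerprints")
    fps = sorted(fps, key=lambda fp: fp.compound_id)
    ids, x = _bit_matrix(fps)
    z = linkage(x, method="centroid")
    return ClusterTree(ids=ids, merges=z)


def cut_clusters(tree: ClusterTree, k: int | None = None, height: float | None = None) -> dict[str, int]:
    """Partition the leaves into k clusters (or cut at a merge height)."""
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    if k is not None:
        if not 1 <= k <= tree.n_leaves:
            raise ValueError(f"k must be in [1, {tree.n_leaves}], got {k}")
        labels = fcluster(tree.merges, t=k, criterion="maxclust")
    else:
        labels = fcluster(tree.merges, t=height, criterion="distance")
    return {cid: int(lab) for cid, lab in zip(tree.ids, labels)}


def novelty_report(
    assignment: Mapping[str, int], query_ids: Sequence[str]
) -> dict[str, dict]:
    """Cluster co-members of each query; novel = alone or with queries only."""
    out: dict[str, dict] = {}
    queries = set(query_ids)
    for q in query_ids:
        if q not in assignment:
            raise KeyError(f"query {q!r} not in the clustering")
        lab = assignment[q]
        mates = [c for c, l_ in assignment.items() if l_ == lab and c != q]
        out[q] = {
            "cluster": lab,
            "co_members": sorted(mates),
            "novel": all(m in queries for m in mates),
        }
    return out


def anchor_conservation(
    anchors: Sequence[Anchor], table: Mapping[str, int]
) -> dict[str, float]:
    """Mean residue conservation grade per anchor, to one decimal.

    ``table`` maps residue keys (``chain:number``) to integer grades
    1-9; every anchor residue must be present.
    """
    out: dict[str, float] = {}
    for anchor in anchors:
        grades = []
        missing = []
        for r in anchor.residues:
            g = table.get(r.key)
            if g is None:
                missing.append(r.key)
            else:
                if not 1 <= int(g) <= 9:
                    raise ValueError(f"grade for {r.key} out of range 1-9: {g}")
                grades.append(int(g))
        if missing:
            raise ValueError(
                f"anchor {anchor.anchor_id}: residues missing from the "
                f"conservation table: {missing}"
            )
        out[anchor.anchor_id] = round(sum(grades) / len(grades), 1)
    return out


def read_conservation_table(path: str | Path) -> dict[str, int]:
    """2-column TSV: residue key (chain:number), grade 1-9."""
    out: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("residue"):
            continue
        key, grade = line.split("\t")[:2]
        out[key] = int(grade)
    return out
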