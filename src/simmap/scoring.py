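"""Anchor matching, the SiMMap score, ranking, and enrichment.

The SiMMap score of compound x is

    S(x) = sum_a AS_a(x) + (-0.001) * E(x) / M**0.5

where AS_a(x) is 1 if the compound matches anchor a and 0 otherwise;
for a combined EH anchor a hydrogen-bond-only match scores 0.5 (an
electrostatic contact scores the full 1). E(x) is the docking score
(negative = favourable) and M the heavy-atom count; the sqrt(M)
divisor damps the size bias of raw docking energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .interactions import InteractionRecord
from .profiles import Anchor

__all__ = [
    "CompoundScore",
    "EnrichmentResult",
    "match_anchor",
    "simmap_score",
    "score_compound",
    "rank_compounds",
    "enrichment",
]

ENERGY_WEIGHT = -0.001


@dataclass
class CompoundScore:
    compound_id: str
    anchor_scores: dict[str, float]  # anchor_id -> AS in {0, 0.5, 1}
    docking_score: float
    atom_count: int
    simmap_score: float
    rank: int = 0


@dataclass
class EnrichmentResult:
    method: str  # "docking" or "simmap"
    hit_counts: list[tuple[int, int]]  # (top_k, n_actives_found)
    hit_rates: list[tuple[int, float]] = field(default_factory=list)


def match_anchor(records: Sequence[InteractionRecord], anchor: Anchor) -> float:
    """Anchor score AS_a(x) of one compound against one anchor.

    Non-EH anchor: 1 iff the compound has >=1 record of the anchor's
    type with any anchor residue, else 0. EH anchor: 1 for an
    electrostatic contact with an anchor residue (with or without
    hydrogen bonds), 0.5 for hydrogen bonds only, 0 otherwise.
    """
    keys = {r.key for r in anchor.residues}
    if anchor.itype == "EH":
        has_e = any(r.itype == "E" and r.residue.key in keys for r in records)
        if has_e:
            return 1.0
        has_h = any(r.itype == "H" and r.residue.key in keys for r in records)
        return 0.5 if has_h else 0.0
    hit = any(r.itype == anchor.itype and r.residue.key in keys for r in records)
    return 1.0 if hit else 0.0


def simmap_score(
    anchor_scores: Mapping[str, float] | Sequence[float],
    docking_score: float,
    atom_count: int,
) -> float:
    """S = sum(AS) - 0.001 * E / sqrt(M)."""
    if atom_count < 1:
        raise ValueError("atom count M must be >= 1")
    values = (
        anchor_scores.values() if isinstance(anchor_scores, Mapping) else anchor_scores
    )
    return float(sum(values) + ENERGY_WEIGHT * docking_score / math.sqrt(atom_count))


def score_compound(
    compound_id: str,
    records: Sequence[InteractionRecord],
    anchors: Sequence[Anchor],
    docking_score: float,
    atom_count: int,
) -> CompoundScore:
    anchor_scores = {a.anchor_id: match_anchor(records, a) for a in anchors}
    return CompoundScore(
        compound_id=compound_id,
        anchor_scores=anchor_scores,
        docking_score=docking_score,
        atom_count=atom_count,
        simmap_score=simmap_score(anchor_scores, docking_score, atom_count),
    )


def rank_compounds(scores: Sequence[CompoundScore]) -> list[CompoundScore]:
    """Descending S; ties by lower docking energy, then compound id."""
    if not scores:
        raise ValueError("no compounds to rank")
    ordered = sorted(
        scores, key=lambda s: (-s.simmap_score, s.docking_score, s.compound_id)
    )
    for i, s in enumerate(ordered, start=1):
        s.rank = i
    return ordered


def enrichment(
    ranked_ids: Sequence[str],
    active_ids: Sequence[str],
    cutoffs: Sequence[int],
    method: str = "simmap",
) -> EnrichmentResult:
    """Actives found among the top k for each cutoff k.

    The hit rate at k is (#actives in top k) / k; a cutoff larger than
    the list is evaluated over the full list (still divided by k as
    given, capped at the list length).
    """
    actives = set(active_ids)
    if not actives:
        raise ValueError("no active compounds given")
    missing = actives - set(ranked_ids)
    if missing:
        raise ValueError(f"actives not present in ranking: {sorted(missing)}")
    counts = []
    rates = []
    for k in cutoffs:
        kk = min(k, len(ranked_ids))
        found = sum(1 for cid in ranked_ids[:kk] if cid in actives)
        counts.append((k, found))
        rates.append((k, found / kk))
    return EnrichmentResult(method=method, hit_counts=counts, hit_rates=rates)
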