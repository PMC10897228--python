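"""Combine motif, conservation, disorder and structural evidence into tiers.

A bare anchor match is weak evidence: the F/L-plus-acidic motif is neither
sensitive nor specific on its own.  Candidates are therefore tiered by how
many of the client-defining criteria they satisfy rather than given a
composite score with invented weights:

* tier A - motif anchor that is conserved AND disordered (structural
  interface evidence, when present, is carried along as corroboration);
* tier B - motif plus exactly one of {conserved, disordered};
* tier C - motif only.

Within a tier, candidates order by conservation score (descending), then
protein id - a deterministic total order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .motif import MotifHit

DEFAULT_CONSERVATION_THRESHOLD = 0.8


@dataclass
class CandidateRecord:
    protein_id: str
    hit: MotifHit
    conservation_score: Optional[float]
    conserved: bool
    disordered: bool
    has_structure: bool
    tier: str


def _tier(conserved: bool, disordered: bool) -> str:
    n = int(conserved) + int(disordered)
    return {2: "A", 1: "B", 0: "C"}[n]


def rank_candidates(hits: Sequence[MotifHit],
                    conservation: Optional[Mapping[str, Sequence[float]]] = None,
                    disorder: Optional[Mapping[str, Sequence[float]]] = None,
                    reports: Optional[Mapping[str, dict]] = None,
                    known_proteins: Optional[set[str]] = None,
                    conservation_threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
                    disorder_threshold: float = 50.0,
                    ) -> list[CandidateRecord]:
    """Rank motif hits by satisfied client criteria; one record per protein.

    ``conservation`` and ``disorder`` map protein id to per-residue tracks
    (conservation in [0, 1]; disorder on the pLDDT-like 0-100 scale where
    *low* means disordered).  Missing evidence never counts against a
    protein beyond leaving the criterion unsatisfied.  For proteins with
    several hits the best-tiered (then most conserved, then most N-terminal)
    hit represents the protein.  A hit naming a protein absent from
    ``known_proteins`` (when provided) is an error.
    """
    if known_proteins is not None:
        unknown = {h.protein_id for h in hits} - known_proteins
        if unknown:
            raise ValueError(f"hits reference unknown proteins: {sorted(unknown)}")

    per_protein: dict[str, CandidateRecord] = {}
    for hit in hits:
        pid = hit.protein_id
        score: Optional[float] = None
        if conservation is not None and pid in conservation:
            track = conservation[pid]
            if 1 <= hit.anchor_pos <= len(track):
                score = float(track[hit.anchor_pos - 1])
        conserved = (hit.conserved is True) or (
            score is not None and score >= conservation_threshold)
        disordered = hit.disordered is True
        if not disordered and disorder is not None and pid in disorder:
            track = disorder[pid]
            if 1 <= hit.anchor_pos <= len(track):
                disordered = float(track[hit.anchor_pos - 1]) < disorder_threshold
        record = CandidateRecord(
            protein_id=pid, hit=hit, conservation_score=score,
            conserved=conserved, disordered=disordered,
            has_structure=reports is not None and pid in reports,
            tier=_tier(conserved, disordered),
        )
        incumbent = per_protein.get(pid)
        if incumbent is None or _sort_key(record) < _sort_key(incumbent):
            per_protein[pid] = record
    return sorted(per_protein.values(), key=_sort_key)


def _sort_key(rec: CandidateRecord):
    score = rec.conservation_score if rec.conservation_score is not None else -1.0
    return (rec.tier, -score, rec.protein_id, rec.hit.anchor_pos)


def candidates_table(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "protein_id": [r.protein_id for r in records],
        "tier": [r.tier for r in records],
        "anchor_pos": [r.hit.anchor_pos for r in records],
        "anchor_res": [r.hit.anchor_res for r in records],
        "conservation_score": [r.conservation_score for r in records],
        "conserved": [r.conserved for r in records],
        "disordered": [r.disordered for r in records],
        "acidic_nearby": [r.hit.acidic_nearby for r in records],
        "gly_preceding": [r.hit.gly_preceding for r in records],
        "has_structure": [r.has_structure for r in records],
    })
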