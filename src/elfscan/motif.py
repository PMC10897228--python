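"""Scan protein sequences for candidate ELF-pocket binding motifs.

Miro GTPases (MIRO1/2 in human, Gem1 in yeast) recruit client proteins through
a hydrophobic pocket in their first EF-hand/LM (ELM1) domain, termed the ELF
pocket because clients insert a single phenylalanine or leucine side chain
into it.  Known clients share a loose sequence signature around that anchor:

(i)   a conserved F or L anchor residue,
(ii)  (in mammals, at least) an acidic residue (D/E) close by, which can form
      a salt bridge with a conserved arginine on the Miro surface, and
(iii) location within a conserved, disordered loop.

This module provides literal-string scanning (e.g. the crude "FADI" probe used
to mine a mitochondrial proteome inventory for new clients), anchored scanning
over all F/L positions, and per-hit context classification against criteria
(ii)-(iii).  Conservation evidence is layered on separately (see
:mod:`elfscan.conservation` and :mod:`elfscan.ranking`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ACIDIC = {"D", "E"}

#: pLDDT-style disorder threshold: per-residue confidence below this is
#: treated as disordered (low AlphaFold pLDDT correlates with disorder).
DEFAULT_DISORDER_THRESHOLD = 50.0


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence with an optional per-residue confidence track.

    ``disorder`` holds pLDDT-style scores in [0, 100]; *low* values indicate
    likely disorder.
    """

    id: str
    sequence: str
    disorder: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if self.disorder is not None and len(self.disorder) != len(self.sequence):
            raise ValueError(
                f"disorder track length {len(self.disorder)} != sequence length "
                f"{len(self.sequence)} for {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifPattern:
    """Search pattern: anchor residue set, context half-window, optional literal."""

    anchor_set: frozenset = frozenset({"F", "L"})
    window: int = 5
    literal: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor_set", frozenset(self.anchor_set))
        if not self.anchor_set <= AMINO_ACIDS:
            raise ValueError(f"anchor_set must be standard residues, got {self.anchor_set}")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.literal is not None:
            _check_literal(self.literal)


def _check_literal(literal: str) -> None:
    if not literal:
        raise ValueError("literal pattern must be non-empty")
    bad = set(literal) - AMINO_ACIDS
    if bad:
        raise ValueError(f"literal contains non-amino-acid letters: {sorted(bad)}")


@dataclass
class MotifHit:
    """One candidate ELF-binding site, anchored at a 1-based residue index."""

    protein_id: str
    anchor_pos: int  # 1-based
    anchor_res: str
    acidic_nearby: Optional[bool] = None
    acidic_pos: Optional[int] = None  # 1-based
    gly_preceding: Optional[bool] = None
    disordered: Optional[bool] = None
    conserved: Optional[bool] = None
    context: str = ""


def scan_literal(seq: ProteinRecord, literal: str) -> list[MotifHit]:
    """Report every exact (possibly overlapping) occurrence of ``literal``.

    The anchor is the first character of the match, so scanning for "FADI"
    anchors each hit on the phenylalanine.
    """
    _check_literal(literal)
    hits: list[MotifHit] = []
    start = 0
    while True:
        i = seq.sequence.find(literal, start)
        if i == -1:
            break
        hits.append(
            MotifHit(
                protein_id=seq.id,
                anchor_pos=i + 1,
                anchor_res=seq.sequence[i],
                context=_context(seq.sequence, i, len(literal) + 4),
            )
        )
        start = i + 1  # overlapping occurrences all reported
    return hits


def scan_anchored(seq: ProteinRecord, pattern: MotifPattern) -> list[MotifHit]:
    """One hit per residue belonging to the anchor set (context flags unset)."""
    return [
        MotifHit(
            protein_id=seq.id,
            anchor_pos=i + 1,
            anchor_res=res,
            context=_context(seq.sequence, i, pattern.window),
        )
        for i, res in enumerate(seq.sequence)
        if res in pattern.anchor_set
    ]


def classify_context(hit: MotifHit, seq: ProteinRecord, pattern: MotifPattern,
                     disorder_threshold: float = DEFAULT_DISORDER_THRESHOLD) -> MotifHit:
    """Fill a hit's context flags from its sequence neighbourhood.

    ``acidic_nearby`` is true when a D or E lies within ±window of the anchor
    (anchor excluded); ``acidic_pos`` is the nearest such position, downstream
    winning ties (an arbitrary but fixed convention).  ``gly_preceding`` is
    true when the residue immediately N-terminal of the anchor is glycine.
    ``disordered`` is set only when the record carries a confidence track and
    is true when the anchor's score falls below ``disorder_threshold``.

    Idempotent, and independent of any other hit on the same sequence.
    """
    i = hit.anchor_pos - 1
    if not (0 <= i < len(seq.sequence)) or seq.sequence[i] != hit.anchor_res:
        raise ValueError(
            f"hit anchor {hit.anchor_res}{hit.anchor_pos} inconsistent with sequence {seq.id!r}"
        )
    w = pattern.window
    best_pos: Optional[int] = None
    best_dist = w + 1
    for j in range(max(0, i - w), min(len(seq.sequence), i + w + 1)):
        if j == i or seq.sequence[j] not in ACIDIC:
            continue
        dist = abs(j - i)
        # downstream (C-terminal, j > i) wins ties by strict-inequality order:
        # scan is left-to-right, so replace an upstream tie with the later one
        if dist < best_dist or (dist == best_dist and j > i):
            best_dist = dist
            best_pos = j
    disordered = None
    if seq.disorder is not None:
        disordered = seq.disorder[i] < disorder_threshold
    return replace(
        hit,
        acidic_nearby=best_pos is not None,
        acidic_pos=None if best_pos is None else best_pos + 1,
        gly_preceding=i > 0 and seq.sequence[i - 1] == "G",
        disordered=disordered,
        context=_context(seq.sequence, i, w),
    )


def scan_proteome(proteome: Iterable[ProteinRecord], pattern: MotifPattern,
                  disorder_threshold: float = DEFAULT_DISORDER_THRESHOLD,
                  ) -> tuple[pd.DataFrame, int]:
    """Scan every record and return (hit table, distinct proteins with >=1 hit).

    Literal mode when ``pattern.literal`` is set, otherwise anchored scanning
    followed by context classification.  Row order is deterministic: input
    record order, then anchor position.
    """
    proteome = list(proteome)
    if not proteome:
        raise ValueError("proteome must be non-empty")
    seen: set[str] = set()
    for rec in proteome:
        if rec.id in seen:
            raise ValueError(f"duplicate protein id in proteome: {rec.id!r}")
        seen.add(rec.id)

    rows = []
    proteins_with_hits: set[str] = set()
    for rec in proteome:
        if not rec.sequence:
            continue
        if pattern.literal is not None:
            hits = scan_literal(rec, pattern.literal)
            hits = [classify_context(h, rec, pattern, disorder_threshold) for h in hits]
        else:
            hits = [
                classify_context(h, rec, pattern, disorder_threshold)
                for h in scan_anchored(rec, pattern)
            ]
        if hits:
            proteins_with_hits.add(rec.id)
        rows.extend(vars(h) for h in hits)
    columns = ["protein_id", "anchor_pos", "anchor_res", "context", "acidic_nearby",
               "acidic_pos", "gly_preceding", "disordered", "conserved"]
    table = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    return table, len(proteins_with_hits)


def read_fasta(path: str | Path, disorder: Optional[dict[str, Sequence[float]]] = None,
               ) -> list[ProteinRecord]:
    """Load a multi-record FASTA into ProteinRecords (uppercased sequences)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        track = disorder.get(rec.id) if disorder else None
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), track))
    return records


def read_disorder_tsv(path: str | Path) -> dict[str, list[float]]:
    """Read per-residue disorder scores from a 2-column TSV of ``id:pos`` and score.

    Positions are 1-based and must be contiguous from 1 per protein.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["key", "score"], comment="#")
    tracks: dict[str, dict[int, float]] = {}
    for key, score in zip(df["key"], df["score"]):
        pid, pos = str(key).rsplit(":", 1)
        tracks.setdefault(pid, {})[int(pos)] = float(score)
    out: dict[str, list[float]] = {}
    for pid, scores in tracks.items():
        n = max(scores)
        if sorted(scores) != list(range(1, n + 1)):
            raise ValueError(f"disorder positions for {pid!r} not contiguous from 1")
        out[pid] = [scores[p] for p in range(1, n + 1)]
    return out


def write_hits_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def _context(sequence: str, i: int, w: int) -> str:
    return sequence[max(0, i - w): i + w + 1]
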