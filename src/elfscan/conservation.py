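"""Per-residue conservation from multiple sequence alignments.

Client-binding surfaces of Miro and the Miro-binding motifs of its clients
are strongly conserved; mapping per-column conservation of an MSA onto the
human reference sequence is how anchor residues (e.g. a key phenylalanine)
and binding pockets are flagged as conserved.  The homolog set is trimmed to
the top-N sequences most similar to the reference (N = 1000 by convention)
before scoring.

Scoring uses the Jensen-Shannon divergence between each column's residue
distribution and a background distribution, normalized so that a fully
conserved column scores exactly 1 and a background-like column scores 0.
Gaps are excluded from column distributions; columns where more than half the
rows are gapped are flagged as low-coverage.

Also provided: a co-occurrence statistic for presence/absence of two sequence
modules across species (agreement fraction and the phi coefficient), used to
quantify the coupled evolution of a client's pocket-anchor motif and its
Miro-facing beta-strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import isnan, log
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .motif import AMINO_ACIDS

GAP = "-"
_ALPHABET = sorted(AMINO_ACIDS)
_INDEX = {a: k for k, a in enumerate(_ALPHABET)}

DEFAULT_TOP_N = 1000
LOW_COVERAGE_GAP_FRACTION = 0.5


@dataclass
class Alignment:
    """An MSA as (id, aligned sequence) rows with one designated reference row."""

    rows: list[tuple[str, str]]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
        if self.reference_id not in {rid for rid, _ in self.rows}:
            raise ValueError(f"reference id {self.reference_id!r} not among rows")

    @property
    def reference_row(self) -> str:
        return next(s for rid, s in self.rows if rid == self.reference_id)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])


@dataclass
class ConservationTrack:
    """Scores in [0, 1] per ungapped reference residue, plus per-column gap fraction."""

    reference_id: str
    scores: np.ndarray
    gap_fraction: np.ndarray
    low_coverage: np.ndarray  # boolean, gap fraction above threshold

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("conservation scores must lie in [0, 1]")


@dataclass
class PresenceMatrix:
    """Presence/absence of two sequence modules across a common species set."""

    species: list[str]
    module_a: np.ndarray
    module_b: np.ndarray

    def __post_init__(self) -> None:
        self.module_a = np.asarray(self.module_a, dtype=bool)
        self.module_b = np.asarray(self.module_b, dtype=bool)
        if not (len(self.species) == len(self.module_a) == len(self.module_b)):
            raise ValueError("species, module_a and module_b must have equal lengths")


def read_alignment(path: str | Path, reference_id: str, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA ('fasta') or Stockholm ('stockholm') file."""
    aln = AlignIO.read(str(path), fmt)
    rows = [(rec.id, str(rec.seq).upper()) for rec in aln]
    return Alignment(rows=rows, reference_id=reference_id)


def percent_identity_to_reference(aln: Alignment) -> dict[str, float]:
    """Percent identity of each row to the reference over reference-ungapped columns."""
    ref = aln.reference_row
    ref_cols = [j for j, c in enumerate(ref) if c != GAP]
    out = {}
    for rid, s in aln.rows:
        matches = sum(1 for j in ref_cols if s[j] == ref[j])
        out[rid] = 100.0 * matches / len(ref_cols) if ref_cols else 0.0
    return out


def select_top_homologs(aln: Alignment, n: int = DEFAULT_TOP_N,
                        ranks: Optional[Sequence[str]] = None) -> Alignment:
    """Keep the reference plus the ``n`` homologs most similar to it.

    ``ranks`` may supply a pre-ranked id order (best first, reference excluded
    or included - it is always kept).  Otherwise rows are ranked by percent
    identity to the reference; ties are broken by input order.  When fewer
    than ``n`` homologs are available all are kept and a warning is issued.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    others = [(rid, s) for rid, s in aln.rows if rid != aln.reference_id]
    if ranks is not None:
        order = {rid: k for k, rid in enumerate(ranks)}
        ranked = sorted(others, key=lambda row: order.get(row[0], len(order)))
    else:
        pid = percent_identity_to_reference(aln)
        # stable sort: ties at the cutoff break by input order
        ranked = sorted(others, key=lambda row: -pid[row[0]])
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} homologs available, fewer than requested n={n}",
            stacklevel=2,
        )
    kept = ranked[:n]
    ref_row = (aln.reference_id, aln.reference_row)
    return Alignment(rows=[ref_row] + kept, reference_id=aln.reference_id)


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence, base-2 logs (bounded by 1)."""
    m = 0.5 * (p + q)
    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))
    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20)


def blosum62_background() -> np.ndarray:
    """Amino-acid frequencies underlying the BLOSUM62 matrix (Henikoff 1992)."""
    freqs = {
        "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
        "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
        "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
        "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
    }
    v = np.array([freqs[a] for a in _ALPHABET])
    return v / v.sum()


def column_conservation(aln: Alignment, background: Optional[np.ndarray] = None,
                        ) -> ConservationTrack:
    """Score conservation of each reference-residue column of the MSA.

    Each column's residue distribution (gaps and non-standard letters
    excluded) is compared to the background by Jensen-Shannon divergence and
    normalized by the divergence of a point-mass column, the maximum
    attainable against that background (JSD is convex in the column
    distribution, so the maximum sits at a vertex of the simplex).  Columns
    where the reference itself is gapped are skipped, so the track has one
    score per ungapped reference residue.  Duplicated rows count at full
    weight; no redundancy reweighting is applied.
    """
    if background is None:
        background = uniform_background()
    background = np.asarray(background, dtype=float)
    background = background / background.sum()
    jsd_max = max(_jsd(_point_mass(k), background) for k in range(20))

    scores, gapfrac = [], []
    ref = aln.reference_row
    n_rows = len(aln.rows)
    for j, ref_char in enumerate(ref):
        if ref_char == GAP:
            continue
        counts = np.zeros(20)
        n_gap = 0
        for _, s in aln.rows:
            c = s[j]
            if c == GAP:
                n_gap += 1
            elif c in _INDEX:
                counts[_INDEX[c]] += 1
        total = counts.sum()
        if total == 0:
            scores.append(0.0)
        else:
            p = counts / total
            scores.append(min(1.0, _jsd(p, background) / jsd_max))
        gapfrac.append(n_gap / n_rows)
    scores_arr = np.array(scores)
    gap_arr = np.array(gapfrac)
    return ConservationTrack(
        reference_id=aln.reference_id,
        scores=scores_arr,
        gap_fraction=gap_arr,
        low_coverage=gap_arr > LOW_COVERAGE_GAP_FRACTION,
    )


def _point_mass(k: int) -> np.ndarray:
    p = np.zeros(20)
    p[k] = 1.0
    return p


def map_to_reference(track: ConservationTrack, pos: int) -> float:
    """Score at a 1-based ungapped reference position."""
    if not (1 <= pos <= len(track.scores)):
        raise IndexError(f"position {pos} outside reference length {len(track.scores)}")
    return float(track.scores[pos - 1])


@dataclass
class CooccurrenceResult:
    n_species: int
    agreement: float            # fraction of species where the modules co-occur or co-miss
    phi: Optional[float]        # 2x2 phi coefficient; None when a margin is zero
    table: np.ndarray           # [[both, a_only], [b_only, neither]]


def cooccurrence(pm: PresenceMatrix) -> CooccurrenceResult:
    """Agreement fraction and phi coefficient of two presence/absence vectors.

    agreement = #(a == b) / N, identical to 1 minus the normalized Hamming
    distance.  phi is the Pearson correlation of the two binary variables; it
    is undefined (None) when either module is constant across species.
    """
    a, b = pm.module_a, pm.module_b
    n = len(a)
    if n < 2:
        raise ValueError("co-occurrence needs at least 2 species")
    both = int(np.sum(a & b))
    a_only = int(np.sum(a & ~b))
    b_only = int(np.sum(~a & b))
    neither = int(np.sum(~a & ~b))
    agreement = (both + neither) / n
    denom = (both + a_only) * (b_only + neither) * (both + b_only) * (a_only + neither)
    phi = None if denom == 0 else (both * neither - a_only * b_only) / np.sqrt(denom)
    return CooccurrenceResult(
        n_species=n, agreement=agreement, phi=phi,
        table=np.array([[both, a_only], [b_only, neither]]),
    )


def read_presence_csv(path: str | Path) -> PresenceMatrix:
    """CSV with columns species, module_a, module_b (0/1 or true/false)."""
    df = pd.read_csv(path)
    def to_bool(col):
        return df[col].map(lambda v: str(v).strip().lower() in {"1", "true", "yes"}).to_numpy()
    return PresenceMatrix(
        species=df["species"].astype(str).tolist(),
        module_a=to_bool("module_a"),
        module_b=to_bool("module_b"),
    )


def write_track_tsv(track: ConservationTrack, reference_sequence: str,
                    path: str | Path) -> None:
    """Per-residue TSV: pos, ref_res, score, gap_fraction, low_coverage."""
    if len(reference_sequence) != len(track.scores):
        raise ValueError("reference sequence length does not match track length")
    pd.DataFrame({
        "pos": np.arange(1, len(track.scores) + 1),
        "ref_res": list(reference_sequence),
        "score": track.scores,
        "gap_fraction": track.gap_fraction,
        "low_coverage": track.low_coverage,
    }).to_csv(path, sep="\t", index=False)


def write_attribute_file(track: ConservationTrack, path: str | Path) -> None:
    """Plain per-residue value list consumable by molecular viewers."""
    with open(path, "w") as fh:
        for pos, score in enumerate(track.scores, start=1):
            fh.write(f"{pos}\t{score:.4f}\n")
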