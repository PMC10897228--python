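"""Normalization of fluorescence yeast-two-hybrid (f-Y2H) plate readings.

In an f-Y2H, bait-prey interaction drives beta-galactosidase expression,
read out as well fluorescence of a fluorogenic substrate.  Raw well
fluorescence is normalized to be comparable across plates:

    normalized = (raw - mean(empty-vector wells)) / mean(background-subtracted
                                                         non-empty wells)

so empty-vector wells sit at ~0 and the mean of all interaction wells is
exactly 1 on every plate.  The divisor convention (whether the plate mean
includes the empty-vector wells) is not universal; both behaviours are
implemented, default excluding them, which keeps the statistic dimensionless
and plate-comparable.  Replicate clones of a sample are summarized as
mean +/- SEM (sample SD over clones, n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class Well:
    sample: str
    clone: str
    raw: float
    is_empty_vector: bool = False


@dataclass
class PlateTable:
    wells: list[Well]

    def __post_init__(self) -> None:
        if not any(w.is_empty_vector for w in self.wells):
            raise ValueError("plate has no empty-vector wells")
        if not all(np.isfinite(w.raw) for w in self.wells):
            raise ValueError("raw fluorescence values must be finite")
        if sum(not w.is_empty_vector for w in self.wells) < 2:
            raise ValueError("need at least 2 non-empty-vector wells")


def normalize_fy2h(plate: PlateTable, divisor_includes_empty: bool = False,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize a plate; returns (per-well table, per-sample summary).

    Per well: background (mean of empty-vector wells) is subtracted, then
    wells are divided by the plate mean of background-subtracted values --
    over non-empty wells by default, over all wells when
    ``divisor_includes_empty`` is set.  A non-positive divisor flags a failed
    plate (no signal above background) and raises.

    The per-sample summary reports the replicate mean, SEM (sample SD over
    clones / sqrt(n)) and n per non-empty sample.
    """
    empty = np.array([w.raw for w in plate.wells if w.is_empty_vector])
    background = float(empty.mean())
    subtracted = np.array([w.raw - background for w in plate.wells])
    if divisor_includes_empty:
        divisor = float(subtracted.mean())
    else:
        divisor = float(subtracted[[not w.is_empty_vector for w in plate.wells]].mean())
    if divisor <= 0:
        raise ValueError(
            f"plate divisor {divisor:.4g} <= 0: no signal above the empty-vector "
            "background; plate failed")
    table = pd.DataFrame({
        "sample": [w.sample for w in plate.wells],
        "clone": [w.clone for w in plate.wells],
        "raw": [w.raw for w in plate.wells],
        "is_empty_vector": [w.is_empty_vector for w in plate.wells],
        "normalized": subtracted / divisor,
    })
    grouped = table[~table["is_empty_vector"]].groupby("sample")["normalized"]
    summary = grouped.agg(
        normalized_mean="mean",
        sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
        n="size",
    ).reset_index()
    summary["sem"] = summary["sd"] / np.sqrt(summary["n"])
    summary = summary.drop(columns="sd")
    return table, summary


def read_plate_csv(path: str | Path) -> PlateTable:
    """CSV with columns sample, clone, raw, is_empty_vector."""
    df = pd.read_csv(path)
    wells = [
        Well(
            sample=str(r["sample"]),
            clone=str(r["clone"]),
            raw=float(r["raw"]),
            is_empty_vector=str(r["is_empty_vector"]).strip().lower() in {"1", "true", "yes"},
        )
        for _, r in df.iterrows()
    ]
    return PlateTable(wells)


def write_summary_csv(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False)
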