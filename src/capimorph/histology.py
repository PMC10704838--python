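"""Immune-cell quantification and semiquantitative histology scoring.

Covers the light-microscopy readouts of the biopsy workup: manual counts
of marker-positive immune cells (CD68, CD169/SIGLEC1, CD206, CD45, CD8)
over ten high-power fields at 400x, the 0-3 type-2b-fiber atrophy rubric,
sarcolemmal MHC-class-I upregulation scoring, and fiber-type composition
from ATPase typing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_FIELDS = 10
FIBER_TYPES = ("1", "2a", "2b")


@dataclass
class CellCountRecord:
    """One marker's manual counts over ten high-power fields."""

    sample_id: str
    marker: str
    per_field_counts: tuple[int, ...]
    total_per_10hpf: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.per_field_counts) != N_FIELDS:
            raise ValueError(
                f"{self.marker}: expected exactly {N_FIELDS} field counts, "
                f"got {len(self.per_field_counts)}"
            )
        if any(c < 0 for c in self.per_field_counts):
            raise ValueError("field counts must be >= 0")
        self.total_per_10hpf = int(sum(self.per_field_counts))


def count_cells_per_10hpf(sample_id: str, markers: dict) -> list[CellCountRecord]:
    """Totals per marker from per-field counts (exactly 10 fields each)."""
    return [
        CellCountRecord(sample_id=sample_id, marker=m, per_field_counts=tuple(counts))
        for m, counts in markers.items()
    ]


@dataclass
class FiberTable:
    """Per-fiber annotations for one sample as a DataFrame wrapper.

    Columns: fiber_id, fiber_type (1|2a|2b), area_um2, min_diameter_um,
    mhc1_sarcolemmal (bool), atrophic (bool).
    """

    df: pd.DataFrame

    REQUIRED = ("fiber_id", "fiber_type", "area_um2", "min_diameter_um", "mhc1_sarcolemmal", "atrophic")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"fiber table missing columns: {missing}")
        if len(self.df) == 0:
            raise ValueError("fiber table is empty")
        if (self.df["area_um2"] <= 0).any():
            bad = self.df.index[self.df["area_um2"] <= 0][0]
            raise ValueError(f"non-positive fiber area at row {bad}")
        if (self.df["min_diameter_um"] <= 0).any():
            bad = self.df.index[self.df["min_diameter_um"] <= 0][0]
            raise ValueError(f"non-positive fiber diameter at row {bad}")
        unknown = set(self.df["fiber_type"].astype(str)) - set(FIBER_TYPES)
        if unknown:
            raise ValueError(f"unknown fiber types: {sorted(unknown)}")


def derive_atrophy_flags(df: pd.DataFrame, relative_cutoff: float = 0.5) -> pd.Series:
    """Flag a fiber as atrophic if its area falls below ``relative_cutoff``
    times the median area of same-type fibers. Used in synthetic mode;
    in re-analysis mode the flag is an input."""
    med = df.groupby("fiber_type")["area_um2"].transform("median")
    return df["area_um2"] < relative_cutoff * med


def score_type2b_atrophy(
    fibers: FiberTable,
    small_diameter_cutoff: float = 20.0,
    many_small_fraction: float = 0.30,
) -> int:
    """0-3 grade of selective type-2b-fiber atrophy.

    f = fraction of 2b fibers flagged atrophic: 0 if f = 0; 1 if
    0 < f < 0.15; 2 if 0.15 <= f <= 0.60; grade 3 requires f > 0.60 AND
    "many" small fibers -- operationalised as more than
    ``many_small_fraction`` of 2b fibers under the 20 um minimal-diameter
    cutoff (otherwise the sample stays at grade 2).
    """
    df = fibers.df
    f2b = df[df["fiber_type"].astype(str) == "2b"]
    if len(f2b) == 0:
        raise ValueError("atrophy score undefined: no type-2b fibers")
    f = f2b["atrophic"].mean()
    if f == 0:
        return 0
    if f < 0.15:
        return 1
    if f <= 0.60:
        return 2
    small = (f2b["min_diameter_um"] < small_diameter_cutoff).mean()
    return 3 if small > many_small_fraction else 2


def score_mhc1(fibers: FiberTable, significant_fraction: float = 0.20) -> tuple[int, bool]:
    """Sarcolemmal MHC-class-I upregulation: ordinal score and significance.

    Fractionally: 0 = no positive fibers; 1 = single fibers (< 20%),
    within normal range; 2 = upregulation in at least 20% of fibers,
    judged significant.
    """
    frac = fibers.df["mhc1_sarcolemmal"].mean()
    if frac == 0:
        return 0, False
    if frac < significant_fraction:
        return 1, False
    return 2, True


def fiber_type_composition(fibers: FiberTable) -> dict[str, float]:
    """Percentages per fiber type; type 2 also reported pooled."""
    counts = fibers.df["fiber_type"].astype(str).value_counts()
    total = counts.sum()
    out = {t: 100.0 * counts.get(t, 0) / total for t in FIBER_TYPES}
    out["2"] = out["2a"] + out["2b"]
    return out
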