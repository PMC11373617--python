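"""Immunohistochemistry pathomics: H-scores and Gleason/ISUP mapping.

Each tissue-microarray core is scored manually as the percentage of weakly,
moderately and strongly stained tumor cells.  The modified H-score weights
these 1/2/3, giving a 0-300 scale.  Per patient and marker, the average and
the maximum H-score over the (up to three) tumor cores are the pathomics
features; normal cores are never aggregated.

Whole-mount Gleason patterns (primary + secondary, each 3-5) map to the
five ISUP grade groups; the binary prediction target is ISUP >= 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IhcCore",
    "h_score",
    "aggregate_marker",
    "gs_to_isup",
    "binarize_isup",
    "pathomics_block",
]


@dataclass(frozen=True)
class IhcCore:
    """One IHC core of one marker for one patient."""

    patient_id: str
    marker: str
    core_type: str  # "tumor" | "normal"
    pct_weak: float
    pct_moderate: float
    pct_strong: float

    def __post_init__(self) -> None:
        for p in (self.pct_weak, self.pct_moderate, self.pct_strong):
            if not (0.0 <= p <= 100.0):
                raise ValueError(f"staining percentage {p} outside [0, 100]")
        if self.pct_weak + self.pct_moderate + self.pct_strong > 100.0 + 1e-9:
            raise ValueError("staining percentages sum to more than 100")
        if self.core_type not in ("tumor", "normal"):
            raise ValueError(f"unknown core_type {self.core_type!r}")


def h_score(pct_weak: float, pct_moderate: float, pct_strong: float) -> float:
    """Modified H-score: 1*weak% + 2*moderate% + 3*strong%, range [0, 300].

    The unstained fraction (100 - w - m - s) carries weight zero.
    """
    for p in (pct_weak, pct_moderate, pct_strong):
        if not (0.0 <= p <= 100.0):
            raise ValueError(f"staining percentage {p} outside [0, 100]")
    if pct_weak + pct_moderate + pct_strong > 100.0 + 1e-9:
        raise ValueError("staining percentages sum to more than 100")
    return 1.0 * pct_weak + 2.0 * pct_moderate + 3.0 * pct_strong


def aggregate_marker(cores: list[IhcCore]) -> tuple[float, float]:
    """(H_avg, H_max) over the *tumor* cores of one patient/marker.

    Aggregates whatever tumor cores are available (a missing core simply
    drops out); with no tumor core at all both values are NaN and the
    feature enters downstream imputation.
    """
    scores = [
        h_score(c.pct_weak, c.pct_moderate, c.pct_strong)
        for c in cores
        if c.core_type == "tumor"
    ]
    if not scores:
        return (float("nan"), float("nan"))
    return (float(np.mean(scores)), float(np.max(scores)))


# ISUP grade groups: 3+3 -> 1, 3+4 -> 2, 4+3 -> 3, GS 8 -> 4, GS 9-10 -> 5.
_ISUP_MAP = {
    (3, 3): 1,
    (3, 4): 2,
    (4, 3): 3,
    (4, 4): 4,
    (3, 5): 4,
    (5, 3): 4,
    (4, 5): 5,
    (5, 4): 5,
    (5, 5): 5,
}


def gs_to_isup(primary: int, secondary: int) -> int:
    """Map primary+secondary Gleason patterns to the ISUP grade group."""
    key = (int(primary), int(secondary))
    if key not in _ISUP_MAP:
        raise ValueError(f"invalid Gleason patterns {key}; each must be in {{3,4,5}}")
    return _ISUP_MAP[key]


def binarize_isup(grade: int) -> str:
    """'high' iff ISUP grade >= 3, else 'low'."""
    grade = int(grade)
    if grade not in (1, 2, 3, 4, 5):
        raise ValueError(f"ISUP grade {grade} outside 1..5")
    return "high" if grade >= 3 else "low"


def pathomics_block(cores: pd.DataFrame) -> pd.DataFrame:
    """Patient x marker H-score feature block from a long-format core table.

    `cores` columns: patient, marker, core_type, pct_weak, pct_moderate,
    pct_strong.  Output columns are ``ihc::<marker>::avg`` / ``::max``.
    """
    required = {"patient", "marker", "core_type", "pct_weak", "pct_moderate", "pct_strong"}
    missing = required - set(cores.columns)
    if missing:
        raise ValueError(f"core table missing columns: {sorted(missing)}")
    rows: dict[str, dict[str, float]] = {}
    for (pid, marker), grp in cores.groupby(["patient", "marker"], sort=True):
        core_objs = [
            IhcCore(str(pid), str(marker), r.core_type, r.pct_weak, r.pct_moderate, r.pct_strong)
            for r in grp.itertuples()
        ]
        h_avg, h_max = aggregate_marker(core_objs)
        rows.setdefault(str(pid), {})[f"ihc::{marker}::avg"] = h_avg
        rows.setdefault(str(pid), {})[f"ihc::{marker}::max"] = h_max
    block = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    block = block[sorted(block.columns)]
    block.index.name = "patient"
    return block
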