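"""PEDS phenotype arithmetic and descriptive summaries.

PEDS (percentage of cupules bearing a single spikelet) is scored per
ear as 100 * (cupules without a pedicellate spikelet) / (total
cupules).  Population summaries bin plants into the classes used for
field evaluations: an exact-zero class and upper-closed 10%-wide
classes, plus the ratio of total plants to plants with PEDS > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

BIN_EDGES = tuple(range(0, 101, 10))  # 0, (0,10], (10,20], ..., (90,100]


def compute_peds(single_spikelet_cupules: int, total_cupules: int) -> float:
    """PEDS percentage of one ear."""
    if total_cupules <= 0:
        raise DataError("total cupule count must be positive")
    if not (0 <= single_spikelet_cupules <= total_cupules):
        raise DataError("single-spikelet count must lie in [0, total]")
    return 100.0 * single_spikelet_cupules / total_cupules


@dataclass
class PhenotypeSummary:
    """Binned PEDS distribution of one environment."""

    environment: str
    bin_counts: dict            # label -> count; first label is the 0% class
    total: int
    mean_peds: float
    ratio: float | None         # total : plants with PEDS > 0, or None

    def to_dict(self) -> dict:
        return {"environment": self.environment, "total": self.total,
                "mean_peds": self.mean_peds, "ratio": self.ratio,
                **{f"bin_{k}": v for k, v in self.bin_counts.items()}}


def summarize_phenotypes(peds, environment: str = "") -> PhenotypeSummary:
    """Bin a PEDS vector and report the total : PEDS>0 ratio (2 decimals).

    The 0% class is exact equality; the remaining classes are
    upper-closed intervals (a, b].  The ratio is undefined (None) when
    every plant has PEDS = 0.
    """
    arr = np.asarray(peds, dtype=float)
    if arr.size == 0:
        raise DataError("empty phenotype vector")
    if np.any((arr < 0) | (arr > 100)):
        raise DataError("PEDS values must lie in [0, 100]")
    counts = {"0": int(np.sum(arr == 0))}
    for lo, hi in zip(BIN_EDGES[:-1], BIN_EDGES[1:]):
        counts[f"({lo},{hi}]"] = int(np.sum((arr > lo) & (arr <= hi)))
    n_pos = int(np.sum(arr > 0))
    ratio = round(len(arr) / n_pos, 2) if n_pos > 0 else None
    return PhenotypeSummary(environment=environment, bin_counts=counts,
                            total=len(arr), mean_peds=float(arr.mean()),
                            ratio=ratio)


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])
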