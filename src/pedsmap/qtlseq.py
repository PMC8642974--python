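"""Model/results facade for the bulked-segregant (QTL-seq) arm.

``QtlSeq`` wraps the SNP-index, sliding-window, null-band and
region-calling stages into a statsmodels-style model whose ``fit``
returns a results object carrying every intermediate table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import significance, snp_index
from .errors import DataError
from .significance import CandidateRegion, ThresholdCurve, regions_to_frame


class QtlSeq:
    """Bulked-segregant Δ(SNP-index) analysis of two extreme bulks.

    Parameters
    ----------
    counts : pandas.DataFrame
        Allele-count table (CHROM, POS, HIGH_REF, HIGH_ALT, LOW_REF,
        LOW_ALT; optionally REF/ALT bases), sorted by chromosome and
        position.
    depth_min, depth_max : int
        Per-bulk read-depth pass band; sites outside it are masked.
    window_bp, step_bp, min_snps : int
        Sliding-window geometry and the sparse-window guard.
    """

    def __init__(self, counts: pd.DataFrame, depth_min: int = snp_index.DEPTH_MIN,
                 depth_max: int = snp_index.DEPTH_MAX,
                 window_bp: int = snp_index.WINDOW_BP,
                 step_bp: int = snp_index.STEP_BP,
                 min_snps: int = snp_index.MIN_SNPS):
        counts, n_dropped = snp_index.drop_multiallelic(counts)
        self.counts = counts
        self.n_multiallelic_dropped = n_dropped
        self.depth_min = depth_min
        self.depth_max = depth_max
        self.window_bp = window_bp
        self.step_bp = step_bp
        self.min_snps = min_snps

    def fit(self, curve: ThresholdCurve | None = None, design: str = "F2",
            n_high: int = 50, n_low: int = 50, n_reps: int = 10_000,
            alpha: float = 0.05, seed: int | None = None) -> "QtlSeqResults":
        """Run the full chain: per-SNP indices, windows, null band, regions.

        ``curve`` may be supplied to reuse a precomputed null band;
        otherwise one is simulated for the given bulk design and sizes.
        """
        snps = snp_index.snp_index_table(self.counts, self.depth_min,
                                         self.depth_max)
        windows = snp_index.sliding_windows(snps, self.window_bp, self.step_bp,
                                            self.min_snps)
        if curve is None:
            curve = significance.null_delta_distribution(
                design, n_high, n_low, n_reps=n_reps, seed=seed)
        regions = significance.call_candidate_regions(windows, curve, alpha)
        return QtlSeqResults(self, snps, windows, curve, regions, alpha)


@dataclass
class QtlSeqResults:
    """All tables produced by the QTL-seq chain."""

    model: QtlSeq
    snps: pd.DataFrame
    windows: pd.DataFrame
    curve: ThresholdCurve
    regions_05: list
    alpha: float

    def regions(self, alpha: float | None = None) -> list[CandidateRegion]:
        if alpha is None or alpha == self.alpha:
            return self.regions_05
        return significance.call_candidate_regions(self.windows, self.curve,
                                                   alpha)

    def regions_frame(self, alpha: float | None = None) -> pd.DataFrame:
        return regions_to_frame(self.regions(alpha))

    def filter_counts(self) -> dict:
        """Per-bulk counts of SNPs dropped by the depth filter."""
        out = {"n_snps": len(self.snps),
               "n_multiallelic_dropped": self.model.n_multiallelic_dropped}
        for label in ("high", "low"):
            status = self.snps[f"status_{label}"]
            out[f"{label}_low_depth"] = int((status == snp_index.LOW_DEPTH).sum())
            out[f"{label}_high_depth"] = int((status == snp_index.HIGH_DEPTH).sum())
            out[f"{label}_pass"] = int((status == snp_index.PASS).sum())
        return out

    def summary(self) -> str:
        fc = self.filter_counts()
        lines = [
            "QTL-seq bulked-segregant analysis",
            f"SNPs: {fc['n_snps']} "
            f"(high bulk pass {fc['high_pass']}, low bulk pass {fc['low_pass']}; "
            f"multi-allelic dropped {fc['n_multiallelic_dropped']})",
            f"windows: {len(self.windows)} "
            f"({self.model.window_bp // 1000} kb window, "
            f"{self.model.step_bp // 1000} kb step)",
            f"null band: {self.curve.design} design, bulks "
            f"{self.curve.n_high}/{self.curve.n_low}, "
            f"{self.curve.n_reps} replicates", "",
        ]
        frame = self.regions_frame()
        if len(frame) == 0:
            lines.append(f"no candidate regions at alpha={self.alpha}")
        else:
            lines.append(f"candidate regions at alpha={self.alpha}:")
            show = frame.copy()
            show["Mb"] = (show["start"] / 1e6).round(2).astype(str) + "-" + \
                (show["end"] / 1e6).round(2).astype(str)
            lines.append(show[["chrom", "Mb", "delta_min", "delta_max",
                               "peak_delta", "n_windows", "direction"]]
                         .round(3).to_string(index=False))
        return "\n".join(lines)

    def plot(self, chrom: str, ax=None):
        from .plotting import plot_delta_profile
        return plot_delta_profile(self.windows, self.curve, chrom, ax=ax)
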