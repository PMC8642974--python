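"""SNP-index, depth filtering and sliding-window statistics.

The SNP-index of a bulk at a position is the fraction of aligned reads
carrying the alternate (teosinte) base; Δ(SNP-index) is the high-bulk
index minus the low-bulk index.  Sites whose read depth falls outside
the pass band [depth_min, depth_max] (default [4, 32], i.e. "< 4x or
> 32x filtered out", with 4 and 32 retained) are masked per bulk.
Window averages use a 1 Mb window sliding in 10 kb steps by default,
anchored at position 0 of each chromosome, half-open on the right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

DEPTH_MIN = 4
DEPTH_MAX = 32
WINDOW_BP = 1_000_000
STEP_BP = 10_000
MIN_SNPS = 3

PASS = "pass"
LOW_DEPTH = "low_depth"
HIGH_DEPTH = "high_depth"


@dataclass(frozen=True)
class SnpIndexRecord:
    """Per-SNP indices and filter status for the two bulks."""

    chrom: str
    pos: int
    depth_high: int
    depth_low: int
    index_high: float          # NaN unless status_high == "pass"
    index_low: float
    delta: float               # NaN unless both bulks pass
    status_high: str
    status_low: str


def _status(depth: np.ndarray, depth_min: int, depth_max: int) -> np.ndarray:
    out = np.full(depth.shape, PASS, dtype=object)
    out[depth < depth_min] = LOW_DEPTH
    out[depth > depth_max] = HIGH_DEPTH
    return out


def compute_snp_index(record, depth_min: int = DEPTH_MIN,
                      depth_max: int = DEPTH_MAX) -> SnpIndexRecord:
    """SNP-index of one allele-count record (mapping with CHROM, POS,
    HIGH_REF, HIGH_ALT, LOW_REF, LOW_ALT)."""
    row = pd.DataFrame([dict(record)])
    out = snp_index_table(row, depth_min, depth_max).iloc[0]
    return SnpIndexRecord(
        chrom=str(out["CHROM"]), pos=int(out["POS"]),
        depth_high=int(out["depth_high"]), depth_low=int(out["depth_low"]),
        index_high=float(out["index_high"]), index_low=float(out["index_low"]),
        delta=float(out["delta"]),
        status_high=str(out["status_high"]), status_low=str(out["status_low"]),
    )


def snp_index_table(counts: pd.DataFrame, depth_min: int = DEPTH_MIN,
                    depth_max: int = DEPTH_MAX) -> pd.DataFrame:
    """Vectorised SNP-index over an allele-count table.

    Input columns: CHROM, POS, HIGH_REF, HIGH_ALT, LOW_REF, LOW_ALT
    (REF/ALT base columns are carried through if present).  Adds
    depth_*, index_*, status_* per bulk and delta = index_high -
    index_low where both bulks pass.
    """
    need = ["CHROM", "POS", "HIGH_REF", "HIGH_ALT", "LOW_REF", "LOW_ALT"]
    missing = [c for c in need if c not in counts.columns]
    if missing:
        raise DataError(f"allele-count table lacks columns {missing}")
    for c in need[2:] + ["POS"]:
        vals = np.asarray(counts[c])
        if np.any(vals < 0):
            raise DataError(f"negative values in column {c}")
    if np.any(np.asarray(counts["POS"]) < 1):
        raise DataError("POS must be 1-based (>= 1)")

    out = counts.copy()
    for label in ("high", "low"):
        ref = np.asarray(counts[f"{label.upper()}_REF"], dtype=np.int64)
        alt = np.asarray(counts[f"{label.upper()}_ALT"], dtype=np.int64)
        depth = ref + alt
        status = _status(depth, depth_min, depth_max)
        idx = np.full(len(depth), np.nan)
        ok = status == PASS
        idx[ok] = alt[ok] / depth[ok]
        out[f"depth_{label}"] = depth
        out[f"index_{label}"] = idx
        out[f"status_{label}"] = status
    out["delta"] = out["index_high"] - out["index_low"]
    return out


def drop_multiallelic(counts: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove sites whose REF/ALT are not single bases (biallelic SNPs only)."""
    if "REF" not in counts.columns or "ALT" not in counts.columns:
        return counts, 0
    ok = (counts["REF"].astype(str).str.len() == 1) & \
         (counts["ALT"].astype(str).str.len() == 1) & \
         (~counts["ALT"].astype(str).str.contains(","))
    return counts[ok].reset_index(drop=True), int((~ok).sum())


def _check_sorted(table: pd.DataFrame) -> None:
    chrom = np.asarray(table["CHROM"], dtype=object)
    pos = np.asarray(table["POS"], dtype=np.int64)
    new_chrom = np.concatenate([[True], chrom[1:] != chrom[:-1]])
    seen = set()
    for c, is_new in zip(chrom, new_chrom):
        if is_new:
            if c in seen:
                raise DataError("records not grouped by chromosome; sort first")
            seen.add(c)
    within = np.diff(pos) >= 0
    if not np.all(within | new_chrom[1:]):
        raise DataError("records not sorted by position within chromosome")


def sliding_windows(snps: pd.DataFrame, window_bp: int = WINDOW_BP,
                    step_bp: int = STEP_BP, min_snps: int = MIN_SNPS) -> pd.DataFrame:
    """Sliding-window means of SNP-index and Δ(SNP-index).

    Windows are [k*step, k*step + window) in bp, k = 0, 1, ... per
    chromosome, up to the last window whose start is at or before the
    last SNP.  Means are over passing SNPs only; a window with fewer
    than ``min_snps`` passing SNPs (for the statistic in question) gets
    NaN.  Input must be sorted by (chromosome, position).
    """
    _check_sorted(snps)
    frames = []
    value_cols = ("index_high", "index_low", "delta",
                  "depth_high", "depth_low")
    for chrom, grp in snps.groupby("CHROM", sort=False):
        pos = np.asarray(grp["POS"], dtype=np.int64)
        if len(pos) == 0:
            continue
        k_max = int(pos.max() // step_bp)
        starts = np.arange(0, (k_max + 1) * step_bp, step_bp, dtype=np.int64)
        ends = starts + window_bp
        # membership: start <= POS < end, on the 1-based POS axis
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        block = {"CHROM": chrom, "start": starts, "end": ends}
        n_pass = None
        for col in value_cols:
            vals = np.asarray(grp[col], dtype=float)
            if col.startswith("depth"):
                ok = np.asarray(grp[f"status_{col.split('_')[1]}"]) == PASS
            elif col == "delta":
                ok = np.isfinite(vals)
            else:
                ok = np.asarray(grp[f"status_{col.split('_')[1]}"]) == PASS
            v = np.where(ok, vals, 0.0)
            cs_v = np.concatenate([[0.0], np.cumsum(v)])
            cs_n = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
            cnt = cs_n[hi] - cs_n[lo]
            mean = np.full(len(starts), np.nan)
            enough = cnt >= min_snps
            with np.errstate(invalid="ignore"):
                mean[enough] = (cs_v[hi] - cs_v[lo])[enough] / cnt[enough]
            block[f"mean_{col}"] = mean
            if col == "delta":
                block["n_snps"] = cnt
        frames.append(pd.DataFrame(block))
    if not frames:
        return pd.DataFrame(columns=["CHROM", "start", "end", "n_snps",
                                     "mean_index_high", "mean_index_low",
                                     "mean_delta", "mean_depth_high",
                                     "mean_depth_low"])
    out = pd.concat(frames, ignore_index=True)
    cols = ["CHROM", "start", "end", "n_snps", "mean_index_high",
            "mean_index_low", "mean_delta", "mean_depth_high", "mean_depth_low"]
    return out[cols]
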