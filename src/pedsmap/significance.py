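"""Monte-Carlo null distribution of Δ(SNP-index) and candidate-region calling.

Following the simulation approach introduced for QTL-seq, the null
distribution of Δ(SNP-index) at an unlinked locus is obtained by
simulating, per replicate and bulk, the sampling of bulk individuals'
genotypes, the bulk allele frequency, a read depth from a Poisson
distribution truncated to the depth-filter pass band, and a binomial
alternate-read count.  Quantiles of the simulated Δ are tabulated per
mean depth; windows whose mean Δ falls outside the band at their depth
are significant, and runs of consecutive significant windows are merged
into candidate regions.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .snp_index import DEPTH_MAX, DEPTH_MIN

DESIGNS = ("F2", "BC")


@dataclass
class ThresholdCurve:
    """Depth-stratified null quantiles of Δ(SNP-index).

    ``table`` is indexed by depth with columns lo95/hi95 (2.5 and 97.5
    percentiles) and lo99/hi99 (0.5 and 99.5 percentiles).
    """

    design: str
    n_high: int
    n_low: int
    table: pd.DataFrame
    n_reps: int
    seed: int | None = None
    warnings: list = field(default_factory=list)

    def band(self, depth: float, alpha: float) -> tuple[float, float]:
        """(lower, upper) threshold at the nearest tabulated depth."""
        if alpha not in (0.05, 0.01):
            raise ConfigError(f"alpha must be 0.05 or 0.01 (got {alpha})")
        depths = self.table.index.to_numpy(dtype=float)
        i = int(np.argmin(np.abs(depths - depth)))
        row = self.table.iloc[i]
        return ((row["lo95"], row["hi95"]) if alpha == 0.05
                else (row["lo99"], row["hi99"]))

    def to_frame(self) -> pd.DataFrame:
        out = self.table.reset_index()
        out.insert(0, "design", self.design)
        return out


def _truncated_poisson(lam: float, size: int, rng: np.random.Generator,
                       lo: int = DEPTH_MIN, hi: int = DEPTH_MAX) -> np.ndarray:
    support = np.arange(lo, hi + 1)
    pmf = stats.poisson.pmf(support, lam)
    total = pmf.sum()
    if total <= 0:
        raise ConfigError(f"depth {lam} has no mass in the pass band [{lo}, {hi}]")
    return rng.choice(support, size=size, p=pmf / total)


def _null_bulk_freq(design: str, n: int, size: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Bulk teosinte-allele frequency at an unlinked locus under the null.

    F2: individual dosage in {0,1,2} with prob {1/4,1/2,1/4}; the sum of
    n such dosages is Binomial(2n, 1/2).  BC: dosage in {0,1} with prob
    {1/2,1/2}; the sum is Binomial(n, 1/2) out of 2n alleles.
    """
    if design == "F2":
        return rng.binomial(2 * n, 0.5, size=size) / (2.0 * n)
    if design == "BC":
        return rng.binomial(n, 0.5, size=size) / (2.0 * n)
    raise ConfigError(f"design must be one of {DESIGNS} (got {design!r})")


def simulate_null_deltas(design: str, n_high: int, n_low: int, depth: float,
                         n_reps: int, rng: np.random.Generator,
                         depth_min: int = DEPTH_MIN,
                         depth_max: int = DEPTH_MAX) -> np.ndarray:
    """Δ(SNP-index) replicates at one mean depth under the no-QTL null.

    The per-SNP depth is Poisson(``depth``) truncated to the depth-filter
    pass band, mirroring what the filtered data contain.
    """
    idx = {}
    for label, n in (("high", n_high), ("low", n_low)):
        p = _null_bulk_freq(design, n, n_reps, rng)
        d = _truncated_poisson(depth, n_reps, rng, depth_min, depth_max)
        alt = rng.binomial(d, p)
        idx[label] = alt / d
    return idx["high"] - idx["low"]


def null_delta_distribution(design: str, n_high: int, n_low: int,
                            depths=None, n_reps: int = 10_000,
                            rng: np.random.Generator | None = None,
                            seed: int | None = None) -> ThresholdCurve:
    """Tabulate null Δ(SNP-index) quantiles over a range of mean depths.

    ``depths`` defaults to every integer depth in the pass band.  The
    95%/99% bands at each depth are the 2.5/97.5 and 0.5/99.5
    percentiles of ``n_reps`` simulated Δ values.  To respect the
    expectation that bands narrow with depth, each quantile column is
    made monotone across depth by a running envelope (running minimum
    of upper quantiles, maximum of lower quantiles, from low to high
    depth); with 10,000 replicates the adjustment is within Monte-Carlo
    noise.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    warn: list[str] = []
    if n_reps < 1000:
        msg = f"n_reps={n_reps} < 1000: tail quantiles are unstable"
        warn.append(msg)
        _warnings.warn(msg, stacklevel=2)
    if depths is None:
        depths = np.arange(DEPTH_MIN, DEPTH_MAX + 1)
    depths = np.sort(np.atleast_1d(np.asarray(depths, dtype=float)))
    rows = []
    for lam in depths:
        deltas = simulate_null_deltas(design, n_high, n_low, float(lam),
                                      n_reps, rng)
        lo95, hi95 = np.percentile(deltas, [2.5, 97.5])
        lo99, hi99 = np.percentile(deltas, [0.5, 99.5])
        rows.append({"depth": float(lam), "lo95": lo95, "hi95": hi95,
                     "lo99": lo99, "hi99": hi99})
    table = pd.DataFrame(rows).set_index("depth")
    table["hi95"] = np.minimum.accumulate(table["hi95"])
    table["hi99"] = np.minimum.accumulate(table["hi99"])
    table["lo95"] = np.maximum.accumulate(table["lo95"])
    table["lo99"] = np.maximum.accumulate(table["lo99"])
    # keep 99% band enclosing the 95% band after the envelope
    table["hi99"] = np.maximum(table["hi99"], table["hi95"])
    table["lo99"] = np.minimum(table["lo99"], table["lo95"])
    return ThresholdCurve(design, n_high, n_low, table, n_reps, seed, warn)


@dataclass(frozen=True)
class CandidateRegion:
    """A run of consecutive significant windows merged into one interval."""

    chrom: str
    start: int                # bp, 0-based half-open
    end: int
    peak_delta: float
    delta_min: float
    delta_max: float
    n_windows: int
    alpha: float
    direction: str            # which parent's alleles are enriched in the high bulk

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom, "start": self.start, "end": self.end,
            "peak_delta": self.peak_delta, "delta_min": self.delta_min,
            "delta_max": self.delta_max, "n_windows": self.n_windows,
            "alpha": self.alpha, "direction": self.direction,
        }


def call_candidate_regions(windows: pd.DataFrame, curve: ThresholdCurve,
                           alpha: float = 0.05,
                           merge_overlapping: bool = True) -> list[CandidateRegion]:
    """Threshold windows against the null band and merge significant runs.

    A window is significant when its mean Δ strictly exceeds the upper
    band or falls strictly below the lower band at its mean depth
    (average of the two bulks' mean depths, matched to the nearest
    tabulated depth).  Consecutive significant windows (adjacent at the
    step resolution on the same chromosome) merge into one region; the
    reported Δ range is the min-max of member-window means.  Because
    windows overlap, two runs separated by a single sub-threshold
    window can yield overlapping intervals; with ``merge_overlapping``
    such intervals are further unioned into disjoint regions.
    """
    if windows is None or len(windows) == 0:
        return []
    need = {"CHROM", "start", "end", "mean_delta",
            "mean_depth_high", "mean_depth_low"}
    if not need.issubset(windows.columns):
        raise DataError(f"window table lacks columns {sorted(need - set(windows.columns))}")
    regions: list[CandidateRegion] = []
    for chrom, grp in windows.groupby("CHROM", sort=False):
        grp = grp.sort_values("start")
        delta = np.asarray(grp["mean_delta"], dtype=float)
        depth = 0.5 * (np.asarray(grp["mean_depth_high"], dtype=float)
                       + np.asarray(grp["mean_depth_low"], dtype=float))
        starts = np.asarray(grp["start"], dtype=np.int64)
        ends = np.asarray(grp["end"], dtype=np.int64)
        step = np.min(np.diff(starts)) if len(starts) > 1 else 0
        sig = np.zeros(len(grp), dtype=bool)
        for i in range(len(grp)):
            if not np.isfinite(delta[i]) or not np.isfinite(depth[i]):
                continue
            lo, hi = curve.band(depth[i], alpha)
            sig[i] = delta[i] > hi or delta[i] < lo
        i = 0
        while i < len(sig):
            if not sig[i]:
                i += 1
                continue
            j = i
            while (j + 1 < len(sig) and sig[j + 1]
                   and starts[j + 1] - starts[j] <= max(step, 1)):
                j += 1
            member = delta[i:j + 1]
            peak = member[np.argmax(np.abs(member))]
            regions.append(CandidateRegion(
                chrom=str(chrom), start=int(starts[i]), end=int(ends[j]),
                peak_delta=float(peak),
                delta_min=float(member.min()), delta_max=float(member.max()),
                n_windows=j - i + 1, alpha=alpha,
                direction="teosinte" if peak > 0 else "maize",
            ))
            i = j + 1
    if merge_overlapping:
        regions = _merge_overlapping(regions)
    return regions


def _merge_overlapping(regions: list[CandidateRegion]) -> list[CandidateRegion]:
    merged: list[CandidateRegion] = []
    for r in regions:  # already ordered by (chrom, start)
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            prev = merged[-1]
            peak = max(prev.peak_delta, r.peak_delta, key=abs)
            merged[-1] = CandidateRegion(
                chrom=prev.chrom, start=prev.start, end=max(prev.end, r.end),
                peak_delta=peak,
                delta_min=min(prev.delta_min, r.delta_min),
                delta_max=max(prev.delta_max, r.delta_max),
                n_windows=prev.n_windows + r.n_windows,
                alpha=prev.alpha, direction=prev.direction,
            )
        else:
            merged.append(r)
    return merged


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "peak_delta", "delta_min", "delta_max",
            "n_windows", "alpha", "direction"]
    if not regions:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.to_dict() for r in regions])[cols]
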