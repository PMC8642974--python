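"""Static per-chromosome plots: SNP-index / Δ curves and LOD profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def plot_delta_profile(windows, curve, chrom: str, ax=None):
    """Window means of the two bulks' SNP-index and Δ with the null band."""
    sub = windows[windows["CHROM"] == chrom]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    mb = sub["start"] / 1e6
    ax.plot(mb, sub["mean_index_high"], color="orange", lw=0.8,
            label="high bulk SNP-index")
    ax.plot(mb, sub["mean_index_low"], color="lightgreen", lw=0.8,
            label="low bulk SNP-index")
    ax.plot(mb, sub["mean_delta"], color="tab:blue", lw=1.0,
            label="Δ(SNP-index)")
    depth = 0.5 * (sub["mean_depth_high"] + sub["mean_depth_low"])
    for alpha, color in ((0.05, "red"), (0.01, "green")):
        lo = [curve.band(d, alpha)[0] if d == d else float("nan") for d in depth]
        hi = [curve.band(d, alpha)[1] if d == d else float("nan") for d in depth]
        ax.plot(mb, hi, color=color, lw=0.6, ls="--",
                label=f"null band p<{alpha}")
        ax.plot(mb, lo, color=color, lw=0.6, ls="--")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"chromosome {chrom} position (Mb)")
    ax.set_ylabel("SNP-index / Δ")
    ax.set_ylim(-1.05, 1.05)
    ax.legend(fontsize=6, ncol=2)
    return ax


def plot_lod_profile(scan, lod_threshold: float = 3.0, ax=None):
    """LOD against map position, one panel strip per chromosome."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    offset = 0.0
    ticks, labels = [], []
    for chrom, grp in scan.groupby("chrom", sort=False):
        grp = grp.sort_values("cm")
        ax.plot(grp["cm"] + offset, grp["lod"], lw=1.0)
        ticks.append(offset + grp["cm"].mean())
        labels.append(str(chrom))
        offset += grp["cm"].max() + 10.0
    ax.axhline(lod_threshold, color="red", lw=0.6, ls="--")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("LOD")
    return ax


def save_figure(ax, path) -> None:
    ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(ax.figure)
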