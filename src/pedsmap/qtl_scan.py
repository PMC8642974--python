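"""Inclusive composite interval mapping: single-QTL and epistasis scans.

The engine follows the two-phase ICIM logic.  Phase one selects
background marker cofactors by forward-backward stepwise least squares
on additive/dominance marker scores, with partial-F probability
thresholds.  Phase two walks a cM grid; at each position the phenotype
is adjusted by the fitted effects of all selected cofactors except the
markers flanking the current interval, and the adjusted phenotype is
regressed on the expected additive and dominance scores of a putative
QTL given the flanking marker genotypes (a Haley-Knott-style regression
approximation to the mixture likelihood).  The two-locus scan adds the
four digenic interaction terms (aa, ad, da, dd) and tests them jointly;
the reported AA effect is the additive-by-additive coefficient, whose
positive sign means the parental allele combinations increase the
trait.

Phenotypes are cube-root transformed before scanning to reduce the
skewness of the zero-inflated PEDS distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .linkage import CODES, MISSING, GeneticMap, GenotypeMatrix, kosambi_r

F2_PRIOR = np.array([0.25, 0.5, 0.25])  # maize hom, het, teosinte hom


# ---------------------------------------------------------------------------
# phenotype transform
# ---------------------------------------------------------------------------

def cube_root_transform(peds_percent) -> np.ndarray | float:
    """Cube root of PEDS (%); monotone, maps 0 to 0 and 100 to ~4.6416."""
    arr = np.asarray(peds_percent, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise DataError("PEDS values must lie in [0, 100]")
    out = np.cbrt(arr)
    return float(out) if np.isscalar(peds_percent) else out


# ---------------------------------------------------------------------------
# conditional QTL genotype probabilities
# ---------------------------------------------------------------------------

def _recombination_compose(r1: float, r2: float) -> float:
    """Two-interval recombination under no interference."""
    return r1 * (1 - r2) + r2 * (1 - r1)


def _joint_three_locus(r1: float, r2: float) -> np.ndarray:
    """P(dosage_left, dosage_qtl, dosage_right) for a coupling-phase F2."""
    hap = np.zeros((2, 2, 2))
    for a in (0, 1):
        for q in (0, 1):
            for b in (0, 1):
                t1 = (1 - r1) if a == q else r1
                t2 = (1 - r2) if q == b else r2
                hap[a, q, b] = 0.5 * t1 * t2
    joint = np.zeros((3, 3, 3))
    flat = [(a, q, b) for a in (0, 1) for q in (0, 1) for b in (0, 1)]
    for a1, q1, b1 in flat:
        p1 = hap[a1, q1, b1]
        for a2, q2, b2 in flat:
            joint[a1 + a2, q1 + q2, b1 + b2] += p1 * hap[a2, q2, b2]
    return joint


def conditional_prob_table(r1: float, r2: float) -> np.ndarray:
    """P(QTL genotype | left, right marker codes) as a (4, 4, 3) array.

    Axes 0/1 index the left/right marker code (0=A, 1=H, 2=B,
    3=missing); axis 2 the QTL genotype (maize hom, het, teosinte hom).
    Missing flanks are marginalised; both missing gives the F2 prior.
    """
    for r in (r1, r2):
        if not (0 <= r < 0.5):
            raise ConfigError(f"recombination fraction {r} outside [0, 0.5)")
    joint = _joint_three_locus(r1, r2)
    table = np.zeros((4, 4, 3))
    margin_l = joint.sum(axis=2)      # P(left, qtl)
    margin_r = joint.sum(axis=0)      # P(qtl, right)
    for gl in range(3):
        for gr in range(3):
            cell = joint[gl, :, gr]
            tot = cell.sum()
            table[gl, gr] = cell / tot if tot > 0 else F2_PRIOR
    for gl in range(3):
        cell = margin_l[gl]
        table[gl, 3] = cell / cell.sum()
    for gr in range(3):
        cell = margin_r[:, gr]
        table[3, gr] = cell / cell.sum()
    table[3, 3] = F2_PRIOR
    return table


def qtl_genotype_probs(left: str, right: str, r_left: float, r_right: float,
                       r_flank: float | None = None,
                       tol: float = 1e-6) -> tuple[float, float, float]:
    """Conditional F2 QTL genotype probabilities given flanking codes.

    ``r_flank``, when given, must equal the no-interference composition
    of ``r_left`` and ``r_right``.
    """
    if r_flank is not None:
        expected = _recombination_compose(r_left, r_right)
        if abs(r_flank - expected) > tol:
            raise ConfigError(
                f"r_flank={r_flank} inconsistent with r_left/r_right "
                f"(no-interference composition gives {expected:.6f})")
    code_idx = {**{c: i for i, c in enumerate(CODES)}, MISSING: 3}
    try:
        gl, gr = code_idx[left], code_idx[right]
    except KeyError as exc:
        raise DataError(f"unknown genotype code {exc}") from exc
    table = conditional_prob_table(r_left, r_right)
    p = table[gl, gr]
    return float(p[0]), float(p[1]), float(p[2])


# ---------------------------------------------------------------------------
# marker scores
# ---------------------------------------------------------------------------

def marker_scores(matrix: GenotypeMatrix, marker: str) -> tuple[np.ndarray, np.ndarray]:
    """Additive/dominance scores (x, z) for one marker.

    x = +1 / 0 / -1 for A / H / B; z = 1 for H else 0.  Missing codes
    take their F2 expectations (x = 0, z = 0.5).
    """
    col = matrix.column(marker)
    x = np.zeros(len(col))
    z = np.zeros(len(col))
    x[col == "A"] = 1.0
    x[col == "B"] = -1.0
    z[col == "H"] = 1.0
    z[col == MISSING] = 0.5
    return x, z


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


# ---------------------------------------------------------------------------
# phase one: stepwise cofactor selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseFit:
    """Selected background markers and their joint OLS coefficients."""

    markers: list[str]
    coefficients: dict            # marker -> (a, d)
    intercept: float
    p_in: float
    p_out: float

    def contributions(self, matrix: GenotypeMatrix) -> dict:
        """Per-marker fitted contribution vectors a*x + d*z."""
        out = {}
        for m in self.markers:
            a, d = self.coefficients[m]
            x, z = marker_scores(matrix, m)
            out[m] = a * x + d * z
        return out

    def background(self, matrix: GenotypeMatrix, exclude=()) -> np.ndarray:
        """Fitted cofactor contribution, omitting ``exclude`` markers."""
        n = matrix.n_individuals
        out = np.zeros(n)
        for m, c in self.contributions(matrix).items():
            if m not in exclude:
                out += c
        return out


def _partial_f_p(y: np.ndarray, X_base: np.ndarray, block: np.ndarray) -> float:
    """p-value of the 2-df partial F test for adding ``block`` to ``X_base``."""
    n = len(y)
    _, rss_red = _ols_rss(X_base, y)
    X_full = np.column_stack([X_base, block])
    _, rss_full = _ols_rss(X_full, y)
    df_full = n - X_full.shape[1]
    q = block.shape[1]
    if df_full <= 0 or rss_full <= 0:
        return 0.0
    f = max((rss_red - rss_full) / q, 0.0) / (rss_full / df_full)
    return float(stats.f.sf(f, q, df_full))


def stepwise_marker_selection(y, matrix: GenotypeMatrix, p_in: float = 0.01,
                              p_out: float = 0.02) -> StepwiseFit:
    """Forward-backward stepwise selection over marker (x, z) blocks.

    Deterministic given the input: candidate order and ties are broken
    by (chromosome, bp, marker name).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    meta = matrix.markers.copy()
    meta["_chrom_key"] = meta["chrom"].astype(str)
    order = meta.sort_values(["_chrom_key", "bp", "marker"])["marker"].tolist()
    if n <= 2 * len(order) + 1:
        raise DataError(
            f"n={n} individuals cannot support {len(order)} candidate markers "
            "(2 covariates each); use a larger population or fewer markers")
    blocks = {m: np.column_stack(marker_scores(matrix, m)) for m in order}

    selected: list[str] = []
    while True:
        changed = False
        # forward
        X_base = np.column_stack([np.ones(n)] +
                                 [blocks[m] for m in selected]) \
            if selected else np.ones((n, 1))
        best_m, best_p = None, None
        for m in order:
            if m in selected:
                continue
            p = _partial_f_p(y, X_base, blocks[m])
            if p < p_in and (best_p is None or p < best_p):
                best_m, best_p = m, p
        if best_m is not None:
            selected.append(best_m)
            selected.sort(key=order.index)
            changed = True
        # backward
        while len(selected) > 0:
            worst_m, worst_p = None, -1.0
            for m in selected:
                others = [k for k in selected if k != m]
                X_red = np.column_stack([np.ones(n)] +
                                        [blocks[k] for k in others]) \
                    if others else np.ones((n, 1))
                p = _partial_f_p(y, X_red, blocks[m])
                if p > worst_p:
                    worst_m, worst_p = m, p
            if worst_p > p_out:
                selected.remove(worst_m)
                changed = True
            else:
                break
        if not changed:
            break

    if selected:
        X = np.column_stack([np.ones(n)] + [blocks[m] for m in selected])
        beta, _ = _ols_rss(X, y)
        coefs = {m: (float(beta[1 + 2 * i]), float(beta[2 + 2 * i]))
                 for i, m in enumerate(selected)}
        intercept = float(beta[0])
    else:
        coefs, intercept = {}, float(np.mean(y))
    return StepwiseFit(selected, coefs, intercept, p_in, p_out)


# ---------------------------------------------------------------------------
# phase two: grid scans
# ---------------------------------------------------------------------------

@dataclass
class _GridPosition:
    chrom: str
    cm: float
    left: str                 # flanking marker names (left == right at a marker)
    right: str
    ex: np.ndarray            # expected additive score P(QQ) - P(qq)
    ez: np.ndarray            # expected dominance score P(Qq)


def _code_indices(matrix: GenotypeMatrix, marker: str) -> np.ndarray:
    col = matrix.column(marker)
    idx = np.full(len(col), 3, dtype=np.intp)
    for i, c in enumerate(CODES):
        idx[col == c] = i
    return idx


def _grid_positions(gmap: GeneticMap, matrix: GenotypeMatrix,
                    step_cm: float) -> list[_GridPosition]:
    out: list[_GridPosition] = []
    for chrom in gmap.chromosomes():
        sub = gmap.chromosome(chrom)
        cms = sub["cm"].to_numpy(dtype=float)
        names = sub["marker"].tolist()
        grid = np.arange(cms[0], cms[-1] + 1e-9, step_cm)
        if abs(grid[-1] - cms[-1]) > 1e-9:
            grid = np.append(grid, cms[-1])
        code_cache = {m: _code_indices(matrix, m) for m in names}
        for pos in grid:
            j = int(np.searchsorted(cms, pos + 1e-9)) - 1
            j = max(0, min(j, len(cms) - 2)) if len(cms) > 1 else 0
            at_marker = np.argmin(np.abs(cms - pos))
            if abs(cms[at_marker] - pos) < 1e-7:
                m = names[int(at_marker)]
                table = conditional_prob_table(0.0, 0.0)
                gl = code_cache[m]
                probs = table[gl, gl]
                left = right = m
            else:
                m_l, m_r = names[j], names[j + 1]
                r1 = float(kosambi_r(pos - cms[j]))
                r2 = float(kosambi_r(cms[j + 1] - pos))
                table = conditional_prob_table(min(r1, 0.499999),
                                               min(r2, 0.499999))
                probs = table[code_cache[m_l], code_cache[m_r]]
                left, right = m_l, m_r
            out.append(_GridPosition(
                chrom=str(chrom), cm=float(pos), left=left, right=right,
                ex=probs[:, 0] - probs[:, 2], ez=probs[:, 1]))
    return out


def _lod_fit(y_adj: np.ndarray, regressors: list[np.ndarray],
             null_regressors: list[np.ndarray] | None = None,
             ) -> tuple[float, np.ndarray, float, float]:
    """LOD, coefficients, PVE and RSS of a nested regression comparison."""
    n = len(y_adj)
    ones = np.ones(n)
    X0 = np.column_stack([ones] + (null_regressors or []))
    X1 = np.column_stack([ones] + (null_regressors or []) + regressors)
    _, rss0 = _ols_rss(X0, y_adj)
    beta, rss1 = _ols_rss(X1, y_adj)
    if rss1 <= 0 or rss0 <= 0:
        return 0.0, beta, 0.0, rss1
    lod = max(0.5 * n * np.log10(rss0 / rss1), 0.0)
    tss = float(np.sum((y_adj - y_adj.mean()) ** 2))
    pve = 100.0 * max(rss0 - rss1, 0.0) / tss if tss > 0 else 0.0
    return float(lod), beta, float(pve), rss1


def icim_add_scan(y, gmap: GeneticMap, matrix: GenotypeMatrix,
                  step_cm: float = 1.0, p_in: float = 0.01,
                  p_out: float = 0.02, lod_threshold: float = 3.0,
                  background: StepwiseFit | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-QTL additive+dominance scan along the map grid.

    Returns ``(scan, qtl)``: the full per-position profile and the
    peak summary (one row per contiguous run of positions with LOD at
    or above ``lod_threshold``).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != matrix.n_individuals:
        raise DataError("phenotype length does not match genotype matrix")
    if background is None:
        background = stepwise_marker_selection(y, matrix, p_in, p_out)
    contrib = background.contributions(matrix)
    y_bg = y - sum(contrib.values()) if contrib else y
    rows = []
    for gp in _grid_positions(gmap, matrix, step_cm):
        y_adj = y_bg.copy()
        for m in {gp.left, gp.right}:
            if m in contrib:
                y_adj = y_adj + contrib[m]
        lod, beta, pve, _ = _lod_fit(y_adj, [gp.ex, gp.ez])
        rows.append({"chrom": gp.chrom, "cm": gp.cm, "left": gp.left,
                     "right": gp.right, "lod": lod, "pve": pve,
                     "add": float(beta[1]), "dom": float(beta[2])})
    scan = pd.DataFrame(rows, columns=["chrom", "cm", "left", "right",
                                       "lod", "pve", "add", "dom"])
    qtl = _peaks(scan, gmap, lod_threshold)
    return scan, qtl


def _peaks(scan: pd.DataFrame, gmap: GeneticMap,
           lod_threshold: float) -> pd.DataFrame:
    meta = gmap.table.set_index("marker")
    rows = []
    for chrom, grp in scan.groupby("chrom", sort=False):
        grp = grp.sort_values("cm").reset_index(drop=True)
        above = grp["lod"] >= lod_threshold
        i = 0
        while i < len(grp):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(grp) and above[j + 1]:
                j += 1
            run = grp.iloc[i:j + 1]
            peak = run.loc[run["lod"].idxmax()]
            rows.append({
                "chrom": chrom, "cm": float(peak["cm"]),
                "marker_interval": f"{peak['left']}-{peak['right']}",
                "bp_left": int(meta.loc[peak["left"], "bp"]),
                "bp_right": int(meta.loc[peak["right"], "bp"]),
                "lod": float(peak["lod"]), "pve": float(peak["pve"]),
                "add": float(peak["add"]), "dom": float(peak["dom"]),
            })
            i = j + 1
    cols = ["chrom", "cm", "marker_interval", "bp_left", "bp_right",
            "lod", "pve", "add", "dom"]
    return pd.DataFrame(rows, columns=cols)


def icim_epi_scan(y, gmap: GeneticMap, matrix: GenotypeMatrix,
                  step_cm: float = 5.0, p_in: float = 0.01,
                  p_out: float = 0.02, lod_threshold: float = 5.0,
                  background: StepwiseFit | None = None,
                  prune: bool = True) -> pd.DataFrame:
    """Two-locus epistasis scan over all grid-position pairs.

    For each pair the full digenic model (main a/d terms of both loci
    plus aa, ad, da, dd interactions) is compared against the
    main-terms-only model; pairs with LOD >= ``lod_threshold`` are
    retained.  Same-chromosome pairs must be at least one grid step
    apart.  With ``prune`` the retained pairs are thinned to local LOD
    maxima (no neighbouring pair within one grid step in both
    coordinates has a higher LOD).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != matrix.n_individuals:
        raise DataError("phenotype length does not match genotype matrix")
    if background is None:
        background = stepwise_marker_selection(y, matrix, p_in, p_out)
    grid = _grid_positions(gmap, matrix, step_cm)
    contrib = background.contributions(matrix)
    y_bg = y - sum(contrib.values()) if contrib else y
    rows = []
    for i, g1 in enumerate(grid):
        for g2 in grid[i + 1:]:
            if g1.chrom == g2.chrom and abs(g1.cm - g2.cm) < step_cm - 1e-9:
                continue
            y_adj = y_bg.copy()
            for m in {g1.left, g1.right, g2.left, g2.right}:
                if m in contrib:
                    y_adj = y_adj + contrib[m]
            main = [g1.ex, g1.ez, g2.ex, g2.ez]
            inter = [g1.ex * g2.ex, g1.ex * g2.ez,
                     g1.ez * g2.ex, g1.ez * g2.ez]
            lod, beta, pve, _ = _lod_fit(y_adj, inter, null_regressors=main)
            if lod >= lod_threshold:
                rows.append({
                    "chrom1": g1.chrom, "cm1": g1.cm,
                    "interval1": f"{g1.left}-{g1.right}",
                    "chrom2": g2.chrom, "cm2": g2.cm,
                    "interval2": f"{g2.left}-{g2.right}",
                    "lod": lod, "pve": pve, "aa": float(beta[5]),
                })
    cols = ["chrom1", "cm1", "interval1", "chrom2", "cm2", "interval2",
            "lod", "pve", "aa"]
    out = pd.DataFrame(rows, columns=cols)
    if prune and len(out) > 1:
        out = _prune_pairs(out, step_cm)
    return out.reset_index(drop=True)


def _prune_pairs(pairs: pd.DataFrame, step_cm: float) -> pd.DataFrame:
    keep = np.ones(len(pairs), dtype=bool)
    arr = pairs.to_dict("records")
    for i, a in enumerate(arr):
        for j, b in enumerate(arr):
            if i == j or not keep[i]:
                continue
            near = (a["chrom1"] == b["chrom1"] and a["chrom2"] == b["chrom2"]
                    and abs(a["cm1"] - b["cm1"]) <= step_cm + 1e-9
                    and abs(a["cm2"] - b["cm2"]) <= step_cm + 1e-9)
            if near and (b["lod"] > a["lod"]
                         or (b["lod"] == a["lod"] and j < i)):
                keep[i] = False
                break
    return pairs[keep]


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

class IntervalMapping:
    """Interval-mapping model for a zero-inflated percentage trait.

    Parameters
    ----------
    peds : array-like
        Raw PEDS percentages, one per individual (row order of
        ``genotypes``).
    genotypes : GenotypeMatrix
    genetic_map : GeneticMap
    transform : {"cbrt", "none"}
        Phenotype transform applied before scanning.
    """

    def __init__(self, peds, genotypes: GenotypeMatrix,
                 genetic_map: GeneticMap, transform: str = "cbrt",
                 p_in: float = 0.01, p_out: float = 0.02):
        peds = np.asarray(peds, dtype=float)
        if transform == "cbrt":
            self.endog = cube_root_transform(peds)
        elif transform == "none":
            self.endog = peds.copy()
        else:
            raise ConfigError(f"unknown transform {transform!r}")
        self.peds = peds
        # restrict to markers on the map: cofactor selection must see the
        # same marker set as the scan, or an off-map marker next to a QTL
        # would absorb its effect during background adjustment
        mapped = [m for m in genetic_map.table["marker"]
                  if m in genotypes.genotypes.columns]
        self.genotypes = GenotypeMatrix(
            genotypes.genotypes[mapped],
            genotypes.markers[genotypes.markers["marker"].isin(mapped)]
            .reset_index(drop=True))
        self.map = genetic_map
        self.p_in = p_in
        self.p_out = p_out
        self._background: StepwiseFit | None = None

    def background(self) -> StepwiseFit:
        if self._background is None:
            self._background = stepwise_marker_selection(
                self.endog, self.genotypes, self.p_in, self.p_out)
        return self._background

    def fit(self, step_cm: float = 1.0, lod_threshold: float = 3.0
            ) -> "ScanResults":
        scan, qtl = icim_add_scan(self.endog, self.map, self.genotypes,
                                  step_cm=step_cm, lod_threshold=lod_threshold,
                                  background=self.background())
        return ScanResults(self, scan, qtl, lod_threshold)

    def fit_epistasis(self, step_cm: float = 5.0, lod_threshold: float = 5.0,
                      prune: bool = True) -> "EpistasisResults":
        pairs = icim_epi_scan(self.endog, self.map, self.genotypes,
                              step_cm=step_cm, lod_threshold=lod_threshold,
                              background=self.background(), prune=prune)
        return EpistasisResults(self, pairs, lod_threshold)


@dataclass
class ScanResults:
    """Profile and peak table from the single-QTL scan."""

    model: IntervalMapping
    scan: pd.DataFrame
    qtl: pd.DataFrame
    lod_threshold: float

    def summary(self) -> str:
        lines = ["Single-QTL interval-mapping scan (additive + dominance)",
                 f"individuals: {len(self.model.endog)}, "
                 f"markers: {len(self.model.genotypes.markers)}, "
                 f"background cofactors: {self.model.background().markers}",
                 f"LOD threshold: {self.lod_threshold}", ""]
        if len(self.qtl) == 0:
            lines.append("no QTL above the LOD threshold")
        else:
            lines.append(self.qtl.round(
                {"cm": 1, "lod": 2, "pve": 2, "add": 3, "dom": 3}
            ).to_string(index=False))
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plotting import plot_lod_profile
        return plot_lod_profile(self.scan, lod_threshold=self.lod_threshold,
                                ax=ax)


@dataclass
class EpistasisResults:
    """Retained locus pairs from the two-locus epistasis scan."""

    model: IntervalMapping
    pairs: pd.DataFrame
    lod_threshold: float

    def summary(self) -> str:
        lines = ["Two-locus epistasis scan (additive-by-additive reported as AA)",
                 f"LOD threshold: {self.lod_threshold}", ""]
        if len(self.pairs) == 0:
            lines.append("no epistatic pair above the LOD threshold")
        else:
            lines.append(self.pairs.round(
                {"cm1": 1, "cm2": 1, "lod": 2, "pve": 2, "aa": 3}
            ).to_string(index=False))
        return "\n".join(lines)
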