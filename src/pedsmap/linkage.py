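"""Marker QC, two-point recombination estimation and local map building.

Markers are codominant F2 calls coded A (maize homozygote), H
(heterozygote), B (teosinte homozygote) and '-' (missing).  Marker
order is taken from physical (bp) coordinates; adjacent recombination
fractions are estimated by maximum likelihood from the 3x3 joint
genotype table and converted to centimorgans with the Kosambi map
function.  Markers with distorted segregation (chi-square against
1:2:1) are removed before mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, DataError

CODES = ("A", "H", "B")
MISSING = "-"


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype codes plus marker metadata.

    ``genotypes`` is a DataFrame of codes in {A, H, B, -}; ``markers``
    has columns (marker, chrom, bp), one row per genotype column.
    """

    genotypes: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        cols = set(self.genotypes.columns)
        meta = set(self.markers["marker"])
        if cols != meta:
            raise DataError("marker metadata does not match genotype columns")
        bad = ~self.genotypes.isin(list(CODES) + [MISSING]).all(axis=None)
        if bad:
            raise DataError("genotype codes outside {A, H, B, -}")
        if self.markers["marker"].duplicated().any():
            raise DataError("duplicated marker names in metadata")

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)

    def column(self, marker: str) -> np.ndarray:
        return np.asarray(self.genotypes[marker], dtype=object)

    def counts(self, marker: str) -> tuple[int, int, int]:
        col = self.column(marker)
        return tuple(int(np.sum(col == c)) for c in CODES)


@dataclass
class GeneticMap:
    """Ordered markers with cumulative cM positions and bp anchors."""

    table: pd.DataFrame  # columns: marker, chrom, bp, cm
    dropped: list = field(default_factory=list)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom].reset_index(drop=True)

    def length_cm(self, chrom: str) -> float:
        sub = self.chromosome(chrom)
        return float(sub["cm"].max() - sub["cm"].min())


# ---------------------------------------------------------------------------
# segregation distortion
# ---------------------------------------------------------------------------

def segregation_chi2(counts) -> tuple[float, float]:
    """Pearson chi-square of (n_A, n_H, n_B) against 1:2:1 (2 df)."""
    n_a, n_h, n_b = (int(c) for c in counts)
    n = n_a + n_h + n_b
    if n <= 0:
        raise DataError("all genotypes missing: cannot test segregation")
    expected = np.array([n / 4.0, n / 2.0, n / 4.0])
    chi2, p = stats.chisquare([n_a, n_h, n_b], expected)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# two-point likelihood
# ---------------------------------------------------------------------------

def _joint_class_probs(r: float) -> np.ndarray:
    """P(joint F2 genotype) for two codominant loci at recombination r.

    Returns a 3x3 array indexed by teosinte dosage (0, 1, 2) at each
    locus, obtained by enumerating the four parental-gamete haplotype
    combinations (coupling-phase F1).
    """
    # gamete haplotype probabilities over (allele1, allele2) in {0,1}^2
    p_par = (1.0 - r) / 2.0
    p_rec = r / 2.0
    hap = np.array([[p_par, p_rec], [p_rec, p_par]])  # hap[a1, a2]
    probs = np.zeros((3, 3))
    for a1 in (0, 1):
        for a2 in (0, 1):
            for b1 in (0, 1):
                for b2 in (0, 1):
                    probs[a1 + b1, a2 + b2] += hap[a1, a2] * hap[b1, b2]
    return probs


def _pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    counts = np.zeros((3, 3), dtype=np.int64)
    for i, c1 in enumerate(CODES):
        for j, c2 in enumerate(CODES):
            counts[i, j] = int(np.sum((g1 == c1) & (g2 == c2)))
    return counts


def estimate_recfrac(g1, g2, min_complete: int = 20) -> tuple[float, float]:
    """ML recombination fraction between two codominant F2 markers.

    Maximises the multinomial likelihood of the 9 joint genotype
    classes over r in [0, 0.5] (the double-heterozygote class mixes the
    two phases automatically).  Returns (r_hat, LOD of linkage), with
    LOD = log10 L(r_hat) - log10 L(0.5).
    """
    g1 = np.asarray(g1, dtype=object)
    g2 = np.asarray(g2, dtype=object)
    counts = _pair_counts(g1, g2)
    n = int(counts.sum())
    if n == 0:
        raise DataError("no pairwise-complete individuals for this marker pair")
    if n < min_complete:
        raise DataError(
            f"only {n} pairwise-complete individuals (< {min_complete})")

    def nll(r: float) -> float:
        probs = np.clip(_joint_class_probs(r), 1e-300, None)
        return -float(np.sum(counts * np.log(probs)))

    res = optimize.minimize_scalar(nll, bounds=(1e-9, 0.5), method="bounded",
                                   options={"xatol": 1e-10})
    r_hat = float(res.x)
    # snap to the boundary when the optimum sits against it
    if nll(1e-12) <= res.fun:
        r_hat = 0.0
    lod = (nll(0.5) - nll(r_hat)) / np.log(10.0)
    return r_hat, float(max(lod, 0.0))


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def kosambi_cm(r) -> np.ndarray | float:
    """Kosambi distance: cM = 25 ln((1+2r)/(1-2r)); requires 0 <= r < 0.5."""
    r_arr = np.asarray(r, dtype=float)
    if np.any((r_arr < 0) | (r_arr >= 0.5)):
        raise ConfigError("recombination fraction must be in [0, 0.5)")
    out = 25.0 * np.log((1 + 2 * r_arr) / (1 - 2 * r_arr))
    return float(out) if np.isscalar(r) else out


def kosambi_r(cm) -> np.ndarray | float:
    """Inverse Kosambi: r = tanh(cM/50) / 2; requires cM >= 0."""
    cm_arr = np.asarray(cm, dtype=float)
    if np.any(cm_arr < 0):
        raise ConfigError("map distance must be >= 0")
    out = 0.5 * np.tanh(cm_arr / 50.0)
    return float(out) if np.isscalar(cm) else out


def haldane_cm(r) -> np.ndarray | float:
    """Haldane distance: cM = -50 ln(1-2r); used by the simulator's crossover model."""
    r_arr = np.asarray(r, dtype=float)
    if np.any((r_arr < 0) | (r_arr >= 0.5)):
        raise ConfigError("recombination fraction must be in [0, 0.5)")
    out = -50.0 * np.log(1 - 2 * r_arr)
    return float(out) if np.isscalar(r) else out


def haldane_r(cm) -> np.ndarray | float:
    """Inverse Haldane: r = (1 - exp(-cM/50)) / 2."""
    cm_arr = np.asarray(cm, dtype=float)
    if np.any(cm_arr < 0):
        raise ConfigError("map distance must be >= 0")
    out = 0.5 * (1.0 - np.exp(-cm_arr / 50.0))
    return float(out) if np.isscalar(cm) else out


# ---------------------------------------------------------------------------
# map construction
# ---------------------------------------------------------------------------

def build_local_map(matrix: GenotypeMatrix, alpha_distortion: float = 0.05,
                    min_complete: int = 20,
                    qc_matrix: GenotypeMatrix | None = None) -> GeneticMap:
    """Local genetic map on physically ordered, QC-passing markers.

    Markers failing the 1:2:1 segregation test at ``alpha_distortion``
    are removed (and logged in ``dropped``); surviving markers are
    ordered by bp within chromosome, adjacent recombination fractions
    are ML-estimated and accumulated as Kosambi cM from 0.  A
    chromosome with fewer than two surviving markers is dropped with a
    warning entry.

    In a selected advanced population the distortion screen should be
    run on genotypes of an unselected F2 sample (as in the original
    protocol, where markers were screened on 36 F2 plants before
    genotyping the mapping populations); pass it as ``qc_matrix``.
    Distances are still estimated from ``matrix``.
    """
    qc = qc_matrix if qc_matrix is not None else matrix
    dropped: list[dict] = []
    keep: list[str] = []
    for _, row in matrix.markers.iterrows():
        m = row["marker"]
        if qc_matrix is not None and m not in qc.genotypes.columns:
            dropped.append({"marker": m, "reason": "absent_from_qc_sample"})
            continue
        counts = qc.counts(m)
        if sum(counts) == 0:
            dropped.append({"marker": m, "reason": "all_missing"})
            continue
        chi2, p = segregation_chi2(counts)
        if p < alpha_distortion:
            dropped.append({"marker": m, "reason": "distorted",
                            "chi2": chi2, "p": p})
        else:
            keep.append(m)

    meta = matrix.markers.set_index("marker")
    rows = []
    for chrom in dict.fromkeys(matrix.markers["chrom"]):
        ms = [m for m in keep if meta.loc[m, "chrom"] == chrom]
        ms.sort(key=lambda m: int(meta.loc[m, "bp"]))
        if len(ms) < 2:
            dropped.append({"marker": None, "chrom": chrom,
                            "reason": "fewer_than_two_markers"})
            continue
        cm = 0.0
        rows.append({"marker": ms[0], "chrom": chrom,
                     "bp": int(meta.loc[ms[0], "bp"]), "cm": 0.0})
        for m_prev, m_next in zip(ms[:-1], ms[1:]):
            r_hat, _ = estimate_recfrac(matrix.column(m_prev),
                                        matrix.column(m_next),
                                        min_complete=min_complete)
            r_hat = min(r_hat, 0.4999999)
            cm += kosambi_cm(r_hat)
            rows.append({"marker": m_next, "chrom": chrom,
                         "bp": int(meta.loc[m_next, "bp"]), "cm": float(cm)})
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cm"]),
                      dropped=dropped)
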