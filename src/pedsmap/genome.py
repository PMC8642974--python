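"""Founder-labelled genomes and meiosis for a biparental cross.

A genome is represented per chromosome as two homologs, each an ordered
mosaic of founder segments on the genetic (cM) axis.  Founder labels are
binary: 0 = maize (recurrent parent), 1 = teosinte (donor parent).  A
homolog is stored as a pair of arrays ``(ends, labels)``: ``ends`` holds
the right boundary (cM) of each segment in ascending order, the last
entry equalling the chromosome length, and ``labels`` the founder of
origin of each segment.  Segment ``i`` covers ``[ends[i-1], ends[i])``.

Meiosis follows a no-interference (Haldane) model: the number of
crossovers per chromosome is Poisson with mean equal to the map length
in Morgans, and crossover positions are uniform on the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

MAIZE = 0
TEOSINTE = 1


@dataclass(frozen=True)
class ChromosomeSpec:
    """Physical and genetic extent of one chromosome."""

    name: str
    length_cm: float
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.length_bp <= 0:
            raise ConfigError(
                f"chromosome {self.name!r}: lengths must be positive "
                f"(got {self.length_cm} cM, {self.length_bp} bp)"
            )

    def bp_to_cm(self, pos_bp) -> np.ndarray:
        """Linear interpolation from physical to genetic coordinates."""
        return np.asarray(pos_bp, dtype=float) / self.length_bp * self.length_cm


class Homolog:
    """One chromosome copy: a tiling of founder segments on [0, length)."""

    __slots__ = ("ends", "labels")

    def __init__(self, ends: np.ndarray, labels: np.ndarray):
        self.ends = np.asarray(ends, dtype=float)
        self.labels = np.asarray(labels, dtype=np.int8)

    @classmethod
    def uniform(cls, length_cm: float, founder: int) -> "Homolog":
        return cls(np.array([length_cm]), np.array([founder], dtype=np.int8))

    @property
    def length(self) -> float:
        return float(self.ends[-1])

    def founder_at(self, pos_cm) -> np.ndarray:
        """Founder label at each genetic position (vectorised)."""
        idx = np.searchsorted(self.ends, np.asarray(pos_cm, dtype=float), side="right")
        idx = np.minimum(idx, len(self.ends) - 1)
        return self.labels[idx]

    def merged(self) -> "Homolog":
        """Coalesce adjacent segments with the same founder label."""
        if len(self.labels) == 1:
            return self
        keep = np.empty(len(self.labels), dtype=bool)
        keep[:-1] = self.labels[:-1] != self.labels[1:]
        keep[-1] = True
        return Homolog(self.ends[keep], self.labels[keep])

    def validate(self, length_cm: float) -> None:
        if len(self.ends) == 0:
            raise ConfigError("empty homolog")
        if not np.all(np.diff(self.ends) > 0):
            raise ConfigError("homolog segment ends not strictly increasing")
        if not np.isclose(self.ends[-1], length_cm):
            raise ConfigError(
                f"homolog tiling ends at {self.ends[-1]} cM, expected {length_cm}"
            )
        if not np.all((self.labels == MAIZE) | (self.labels == TEOSINTE)):
            raise ConfigError("founder labels must be 0 (maize) or 1 (teosinte)")


@dataclass
class Genome:
    """Two homologs per chromosome, keyed by chromosome name."""

    chromosomes: dict = field(default_factory=dict)  # name -> (Homolog, Homolog)

    @classmethod
    def founder(cls, specs: list[ChromosomeSpec], label: int) -> "Genome":
        return cls(
            {s.name: (Homolog.uniform(s.length_cm, label),
                      Homolog.uniform(s.length_cm, label)) for s in specs}
        )

    def dosage(self, chrom: str, pos_cm) -> np.ndarray:
        """Count of teosinte alleles (0/1/2) at genetic position(s)."""
        h0, h1 = self.chromosomes[chrom]
        return (h0.founder_at(pos_cm).astype(np.int64)
                + h1.founder_at(pos_cm).astype(np.int64))

    def validate(self, specs: list[ChromosomeSpec]) -> None:
        for s in specs:
            h0, h1 = self.chromosomes[s.name]
            h0.validate(s.length_cm)
            h1.validate(s.length_cm)

    def teosinte_fraction(self, specs: list[ChromosomeSpec]) -> float:
        """Genome-wide fraction of teosinte-labelled material (cM-weighted)."""
        tot = 0.0
        teo = 0.0
        for s in specs:
            for h in self.chromosomes[s.name]:
                starts = np.concatenate([[0.0], h.ends[:-1]])
                seg = h.ends - starts
                teo += float(seg[h.labels == TEOSINTE].sum())
                tot += s.length_cm
        return teo / tot


def _recombine(h0: Homolog, h1: Homolog, xpoints: np.ndarray, start: int) -> Homolog:
    """Splice two homologs at the given crossover positions.

    ``start`` selects the source homolog for the leftmost stretch; the
    source alternates at every crossover point.
    """
    length = h0.length
    bounds = np.concatenate([xpoints, [length]])
    ends_out: list[float] = []
    labs_out: list[int] = []
    lo = 0.0
    src = start
    pair = (h0, h1)
    for hi in bounds:
        if hi <= lo:
            src ^= 1
            continue
        h = pair[src]
        i0 = int(np.searchsorted(h.ends, lo, side="right"))
        i1 = int(np.searchsorted(h.ends, hi, side="left"))
        for j in range(i0, min(i1 + 1, len(h.ends))):
            seg_end = min(float(h.ends[j]), hi)
            if seg_end > lo:
                ends_out.append(seg_end)
                labs_out.append(int(h.labels[j]))
                lo = seg_end
            if seg_end >= hi:
                break
        lo = hi
        src ^= 1
    out = Homolog(np.array(ends_out), np.array(labs_out, dtype=np.int8))
    return out.merged()


def simulate_meiosis(parent: Genome, specs: list[ChromosomeSpec],
                     rng: np.random.Generator) -> dict:
    """One gamete: a recombinant homolog per chromosome.

    Crossover counts are Poisson(length/100) per chromosome, positions
    uniform — i.e. no crossover interference.
    """
    gamete = {}
    for s in specs:
        if s.length_cm <= 0:
            raise ConfigError(f"chromosome {s.name!r} has non-positive length")
        h0, h1 = parent.chromosomes[s.name]
        n_x = rng.poisson(s.length_cm / 100.0)
        start = int(rng.integers(2))
        if n_x == 0:
            gamete[s.name] = (h0, h1)[start]
        else:
            xpts = np.sort(rng.uniform(0.0, s.length_cm, size=n_x))
            gamete[s.name] = _recombine(h0, h1, xpts, start)
    return gamete


def genome_from_gametes(g0: dict, g1: dict) -> Genome:
    return Genome({c: (g0[c], g1[c]) for c in g0})


@dataclass
class Individual:
    """A plant: its genome and (once evaluated) its PEDS phenotype."""

    genome: Genome
    peds: float | None = None
    generation: str = ""

    def dosage(self, chrom: str, pos_cm) -> np.ndarray:
        return self.genome.dosage(chrom, pos_cm)
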