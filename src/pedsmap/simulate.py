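"""Forward simulation of the advanced backcross scheme and bulk sequencing.

The scheme mirrors the development of the mapping populations: an F1
between a maize inbred and teosinte is selfed to give an F2; plants with
PEDS = 100% (exclusively single spikelets) are backcrossed to the maize
parent; each BCnF1 is selfed to a BCnF2 from which PEDS = 100% plants
are again selected, and so on.  Phenotypes follow a censored linear
link: a latent polygenic score (additive + dominance + additive-by-
additive epistasis + Gaussian noise) is clipped to [0, 1] and scaled to
a PEDS percentage, which yields the observed point mass at PEDS = 0.

Bulked sequencing is simulated at the read-count level only: per
diagnostic SNP, the bulk's true teosinte-allele frequency is binomially
sampled at a Poisson depth, with a symmetric base-miscall rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import ConfigError, DataError, SelectionError
from .genome import (MAIZE, TEOSINTE, Genome, Individual, genome_from_gametes,
                     simulate_meiosis)

__all__ = [
    "simulate_peds_phenotype", "advance_generation", "simulate_population",
    "build_bulks", "build_overlapping_bulks", "simulate_bulk_counts",
    "PedsRule", "SimulationResult",
]


# ---------------------------------------------------------------------------
# phenotype link
# ---------------------------------------------------------------------------

def _latent_scores(individuals, config: SimConfig) -> np.ndarray:
    """Genetic part of the latent score for each individual."""
    n = len(individuals)
    g = np.full(n, config.mu, dtype=float)
    xs = np.empty((len(config.qtls), n))
    for j, q in enumerate(config.qtls):
        dos = np.array([ind.dosage(q.chrom, q.pos_cm) for ind in individuals],
                       dtype=float)
        x = 1.0 - dos          # +1 maize hom, 0 het, -1 teosinte hom
        z = (dos == 1).astype(float)
        xs[j] = x
        g += q.a * x + q.d * z
    for e in config.epistasis:
        g += e.aa * xs[e.qtl1] * xs[e.qtl2]
    return g


def simulate_peds_phenotype(individuals, config: SimConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """PEDS percentages under the censored linear link.

    latent = mu + sum_j (a_j x_j + d_j z_j) + sum_kl aa_kl x_k x_l + e,
    e ~ N(0, sigma_e^2);  PEDS = 100 * clip(latent, 0, 1).
    """
    g = _latent_scores(individuals, config)
    e = rng.normal(0.0, config.sigma_e, size=len(individuals))
    peds = 100.0 * np.clip(g + e, 0.0, 1.0)
    for ind, p in zip(individuals, peds):
        ind.peds = float(p)
    return peds


# ---------------------------------------------------------------------------
# generations
# ---------------------------------------------------------------------------

def advance_generation(population, scheme: str, selection_rule, n_offspring: int,
                       config: SimConfig, rng: np.random.Generator,
                       generation: str = "") -> list:
    """Produce the next generation under selfing or backcrossing.

    ``selection_rule`` is a predicate on PEDS (or None for no selection)
    applied to the parent population.  If it matches no plant, a
    :class:`SelectionError` is raised rather than silently relaxing it.
    """
    if not population:
        raise DataError("cannot advance an empty population")
    if scheme not in ("self", "backcross_to_maize"):
        raise ConfigError(f"unknown scheme {scheme!r}")
    if selection_rule is None:
        parents = list(population)
    else:
        parents = [ind for ind in population if ind.peds is not None
                   and selection_rule(ind.peds)]
        if not parents:
            raise SelectionError(
                f"selection produced no parents among {len(population)} plants "
                f"(scheme {scheme!r}, generation {generation!r})"
            )
    specs = config.chromosomes
    maize = Genome.founder(specs, MAIZE)
    offspring = []
    idx = rng.integers(len(parents), size=n_offspring)
    for i in idx:
        p = parents[int(i)]
        g0 = simulate_meiosis(p.genome, specs, rng)
        if scheme == "self":
            g1 = simulate_meiosis(p.genome, specs, rng)
        else:
            g1 = simulate_meiosis(maize, specs, rng)
        offspring.append(Individual(genome_from_gametes(g0, g1),
                                    generation=generation))
    return offspring


def simulate_f2(config: SimConfig, n: int, rng: np.random.Generator) -> list:
    """An unselected F2 sample of the same cross (e.g. for marker QC)."""
    specs = config.chromosomes
    maize = Individual(Genome.founder(specs, MAIZE))
    teo = Individual(Genome.founder(specs, TEOSINTE))
    f1 = Individual(
        genome_from_gametes(simulate_meiosis(maize.genome, specs, rng),
                            simulate_meiosis(teo.genome, specs, rng)),
        generation="F1")
    return advance_generation([f1], "self", None, n, config, rng, "F2")


@dataclass
class SimulationResult:
    """Final mapping population plus the planted truth for recovery checks."""

    population: list
    phenotypes: np.ndarray
    config: SimConfig
    generation: str = ""
    history: list = field(default_factory=list)

    def truth(self) -> dict:
        return {
            "seed": self.config.seed,
            "qtls": [
                {"name": q.name, "chrom": q.chrom, "pos_cm": q.pos_cm,
                 "pos_bp": q.pos_bp, "a": q.a, "d": q.d}
                for q in self.config.qtls
            ],
            "epistasis": [
                {"qtl1": self.config.qtls[e.qtl1].name,
                 "qtl2": self.config.qtls[e.qtl2].name, "aa": e.aa}
                for e in self.config.epistasis
            ],
        }


def simulate_population(config: SimConfig, rng: np.random.Generator | None = None,
                        ) -> SimulationResult:
    """Run the full breeding scheme to the final BCnF2 mapping population."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    specs = config.chromosomes
    select = (lambda thr: (lambda p: p >= thr))(config.selection_peds)

    maize = Individual(Genome.founder(specs, MAIZE), generation="P1")
    teo = Individual(Genome.founder(specs, TEOSINTE), generation="P2")
    f1 = Individual(
        genome_from_gametes(simulate_meiosis(maize.genome, specs, rng),
                            simulate_meiosis(teo.genome, specs, rng)),
        generation="F1")

    f2_name = "F2"
    pop = advance_generation([f1], "self", None,
                             (config.n_final if config.n_backcrosses == 0
                              else config.n_f2), config, rng, f2_name)
    peds = simulate_peds_phenotype(pop, config, rng)
    history = [("F2", len(pop))]

    for b in range(1, config.n_backcrosses + 1):
        f1_name = f"BC{b}F1"
        f2_name = f"BC{b}F2"
        pop = advance_generation(pop, "backcross_to_maize", select,
                                 config.n_bc_f1, config, rng, f1_name)
        history.append((f1_name, len(pop)))
        n = (config.n_final if b == config.n_backcrosses else config.n_f2)
        pop = advance_generation(pop, "self", None, n, config, rng, f2_name)
        peds = simulate_peds_phenotype(pop, config, rng)
        history.append((f2_name, len(pop)))

    return SimulationResult(pop, peds, config, generation=f2_name, history=history)


# ---------------------------------------------------------------------------
# bulks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedsRule:
    """A half-open/closed PEDS interval, e.g. '>90', '=0', '(0,10]'."""

    lo: float = 0.0
    hi: float = 100.0
    lo_inclusive: bool = True
    hi_inclusive: bool = True

    def __call__(self, peds: float) -> bool:
        lo_ok = peds >= self.lo if self.lo_inclusive else peds > self.lo
        hi_ok = peds <= self.hi if self.hi_inclusive else peds < self.hi
        return lo_ok and hi_ok

    @classmethod
    def parse(cls, text: str) -> "PedsRule":
        text = text.strip().replace(" ", "")
        if text.startswith(">="):
            return cls(lo=float(text[2:]))
        if text.startswith(">"):
            return cls(lo=float(text[1:]), lo_inclusive=False)
        if text.startswith("<="):
            return cls(hi=float(text[2:]))
        if text.startswith("<"):
            return cls(hi=float(text[1:]), hi_inclusive=False)
        if text.startswith("="):
            v = float(text[1:])
            return cls(lo=v, hi=v)
        if text[0] in "([" and text[-1] in ")]":
            lo, hi = text[1:-1].split(",")
            return cls(lo=float(lo), hi=float(hi),
                       lo_inclusive=text[0] == "[",
                       hi_inclusive=text[-1] == "]")
        raise ConfigError(f"cannot parse PEDS rule {text!r}")


def _eligible(population, rule) -> np.ndarray:
    return np.array([i for i, ind in enumerate(population)
                     if ind.peds is not None and rule(ind.peds)], dtype=int)


def build_bulks(population, high_rule, low_rule, n_bulk: int,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n_bulk`` plant indices per bulk, uniformly without replacement.

    Raises :class:`DataError` naming the shortfall when fewer plants are
    eligible than requested.
    """
    out = []
    for label, rule in (("high", high_rule), ("low", low_rule)):
        elig = _eligible(population, rule)
        if len(elig) < n_bulk:
            raise DataError(
                f"{label} bulk: only {len(elig)} eligible plants for a bulk "
                f"of {n_bulk} (shortfall {n_bulk - len(elig)})"
            )
        out.append(np.sort(rng.choice(elig, size=n_bulk, replace=False)))
    return out[0], out[1]


def build_overlapping_bulks(population, rule, n_shared: int, n_unique: int,
                            n_bulks: int, rng: np.random.Generator) -> list:
    """Bulks sharing a common core, as in the three overlapping high bulks
    built from 25 common plus 25 distinct plants each."""
    elig = _eligible(population, rule)
    need = n_shared + n_unique * n_bulks
    if len(elig) < need:
        raise DataError(
            f"only {len(elig)} eligible plants for {n_bulks} overlapping bulks "
            f"needing {need} (shortfall {need - len(elig)})"
        )
    chosen = rng.choice(elig, size=need, replace=False)
    core = chosen[:n_shared]
    return [np.sort(np.concatenate(
        [core, chosen[n_shared + k * n_unique: n_shared + (k + 1) * n_unique]]))
        for k in range(n_bulks)]


# ---------------------------------------------------------------------------
# bulked read counts
# ---------------------------------------------------------------------------

def _bulk_allele_freq(population, ids, chrom: str, pos_cm: np.ndarray) -> np.ndarray:
    dos = np.zeros(len(pos_cm), dtype=float)
    for i in ids:
        dos += population[int(i)].dosage(chrom, pos_cm)
    return dos / (2.0 * len(ids))


def simulate_bulk_counts(population, high_ids, low_ids, config: SimConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Allele-count table for the two bulks over the diagnostic-SNP grid.

    Every SNP is parent-diagnostic: the maize allele is REF, the
    teosinte allele ALT.  Depth is Poisson(lambda) per bulk and SNP;
    the alternate count is Binomial(depth, p(1-eps) + (1-p)eps) with p
    the bulk's true teosinte-allele frequency.
    """
    lam, eps = config.depth, config.error_rate
    frames = []
    snp_pos = config.snp_positions()
    for spec in config.chromosomes:
        pos_bp = snp_pos[spec.name]
        pos_cm = spec.bp_to_cm(pos_bp)
        block = {"CHROM": spec.name, "POS": pos_bp, "REF": "A", "ALT": "T"}
        for label, ids in (("HIGH", high_ids), ("LOW", low_ids)):
            p = _bulk_allele_freq(population, ids, spec.name, pos_cm)
            depth = rng.poisson(lam, size=len(pos_bp))
            alt = rng.binomial(depth, p * (1 - eps) + (1 - p) * eps)
            block[f"{label}_REF"] = depth - alt
            block[f"{label}_ALT"] = alt
        frames.append(pd.DataFrame(block))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# marker genotypes
# ---------------------------------------------------------------------------

def genotype_markers(population, config: SimConfig,
                     marker_positions: dict | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Codominant marker calls (A/H/B) for the final mapping population.

    Returns ``(genotypes, markers)``: genotypes is individuals x markers
    with codes A (maize hom), H, B (teosinte hom); markers holds
    (marker, chrom, bp) metadata ordered by physical position.
    """
    positions = marker_positions or config.marker_positions
    if not positions:
        raise ConfigError("no marker positions declared")
    codes = np.array(["A", "H", "B"])
    cols = {}
    meta = []
    for spec in config.chromosomes:
        bps = positions.get(spec.name, [])
        for k, bp in enumerate(sorted(bps)):
            name = f"PM{spec.name}_{k + 1}"
            cm = float(spec.bp_to_cm(bp))
            dos = np.array([int(ind.dosage(spec.name, cm)) for ind in population])
            cols[name] = codes[dos]
            meta.append({"marker": name, "chrom": spec.name, "bp": int(bp)})
    genotypes = pd.DataFrame(cols)
    genotypes.index = [f"ind{i}" for i in range(len(population))]
    return genotypes, pd.DataFrame(meta)
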