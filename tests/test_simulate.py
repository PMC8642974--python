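"""Breeding scheme, phenotype link, bulks and read-count simulation."""

import numpy as np
import pytest

from pedsmap import (ChromosomeSpec, DataError, PedsRule, QtlSpec,
                     SelectionError, SimConfig, advance_generation,
                     build_bulks, build_overlapping_bulks, default_config,
                     simulate_bulk_counts, simulate_peds_phenotype,
                     simulate_population, single_qtl_config)
from pedsmap.genome import MAIZE, TEOSINTE, Genome, Individual
from pedsmap.qtl_scan import cube_root_transform


def _mini_config(seed=1, **kw):
    base = dict(
        seed=seed,
        chromosomes=[ChromosomeSpec("1", 100.0, 100_000_000)],
        qtls=[QtlSpec("1", 50.0, 50_000_000, a=-0.5, d=-0.2)],
        mu=0.5, sigma_e=0.05,
    )
    base.update(kw)
    return SimConfig(**base)


def _plants(peds_values, cfg):
    pop = []
    for p in peds_values:
        ind = Individual(Genome.founder(cfg.chromosomes, MAIZE))
        ind.peds = float(p)
        pop.append(ind)
    return pop


# -- generations -----------------------------------------------------------

def test_selfing_homozygous_maize_stays_maize(rng):
    cfg = _mini_config()
    pop = [Individual(Genome.founder(cfg.chromosomes, MAIZE))
           for _ in range(10)]
    kids = advance_generation(pop, "self", None, 50, cfg, rng)
    for k in kids:
        assert k.genome.teosinte_fraction(cfg.chromosomes) == 0.0


def test_backcross_dosage_is_mendelian(rng):
    cfg = _mini_config()
    f1 = Individual(Genome({
        "1": (Genome.founder(cfg.chromosomes, MAIZE).chromosomes["1"][0],
              Genome.founder(cfg.chromosomes, TEOSINTE).chromosomes["1"][0])}))
    kids = advance_generation([f1], "backcross_to_maize", None, 10_000,
                              cfg, rng)
    dos = np.array([int(k.dosage("1", 30.0)) for k in kids])
    assert set(np.unique(dos)) <= {0, 1}
    assert abs(dos.mean() - 0.5) < 0.02


def test_selection_with_no_matches_raises(rng):
    cfg = _mini_config()
    pop = _plants([0.0] * 20, cfg)
    with pytest.raises(SelectionError, match="no parents"):
        advance_generation(pop, "backcross_to_maize",
                           lambda p: p >= 100.0, 10, cfg, rng)


def test_empty_population_rejected(rng):
    with pytest.raises(DataError):
        advance_generation([], "self", None, 5, _mini_config(), rng)


# -- phenotype link --------------------------------------------------------

def test_all_maize_with_negative_effects_is_censored_at_zero(rng):
    cfg = _mini_config(mu=0.0, sigma_e=1e-6)
    pop = [Individual(Genome.founder(cfg.chromosomes, MAIZE))
           for _ in range(20)]
    peds = simulate_peds_phenotype(pop, cfg, rng)
    assert np.all(peds == 0.0)


def test_default_bc3f2_zero_inflation_in_observed_band(default_sim):
    """Between 1/20 and 1/12 of plants show any single spikelets."""
    frac = np.mean(default_sim.phenotypes > 0)
    assert 1 / 20 <= frac <= 1 / 12


def test_planted_h2_recovered_by_variance_decomposition(f2_sample):
    """The single-QTL link is calibrated to ~35% of cube-root variance."""
    cfg, pop = f2_sample
    rng = np.random.default_rng(99)
    peds = simulate_peds_phenotype(pop, cfg, rng)
    y = cube_root_transform(peds)
    q = cfg.qtls[0]
    dos = np.array([float(ind.dosage(q.chrom, q.pos_cm)) for ind in pop])
    x = 1.0 - dos
    z = (dos == 1).astype(float)
    X = np.column_stack([np.ones(len(y)), x, z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    h2 = 1 - (resid @ resid) / np.sum((y - y.mean()) ** 2)
    assert abs(h2 - 0.35) < 0.05


def test_background_teosinte_declines_but_qtl_keeps_segregating():
    cfg = single_qtl_config(17)
    cfg.n_f2 = 2000
    cfg.n_bc_f1 = 100
    cfg.n_final = 400
    sim = simulate_population(cfg)
    q = cfg.qtls[0]
    dos = np.array([int(ind.dosage(q.chrom, q.pos_cm))
                    for ind in sim.population])
    # the selected QTL still segregates in all three classes
    for k in (0, 1, 2):
        assert np.mean(dos == k) > 0.05
    # unlinked chromosomes are nearly fixed for maize after 3 backcrosses
    frac = np.mean([ind.genome.teosinte_fraction(cfg.chromosomes[:2])
                    for ind in sim.population[:200]])
    assert frac < 0.15


def test_simulation_is_bit_reproducible():
    cfg1 = single_qtl_config(123)
    cfg1.n_f2 = 300
    cfg1.n_final = 300
    sim1 = simulate_population(cfg1)
    cfg2 = single_qtl_config(123)
    cfg2.n_f2 = 300
    cfg2.n_final = 300
    sim2 = simulate_population(cfg2)
    assert np.array_equal(sim1.phenotypes, sim2.phenotypes)
    q = cfg1.qtls[0]
    d1 = [int(i.dosage(q.chrom, q.pos_cm)) for i in sim1.population]
    d2 = [int(i.dosage(q.chrom, q.pos_cm)) for i in sim2.population]
    assert d1 == d2


# -- bulk construction -----------------------------------------------------

def test_bulk_shortfall_raises_named_error(rng):
    cfg = _mini_config()
    pop = _plants([0.0] * 60, cfg)
    with pytest.raises(DataError, match="shortfall"):
        build_bulks(pop, PedsRule.parse(">90"), PedsRule.parse("=0"), 50, rng)


def test_high_rule_is_strict_inequality(rng):
    cfg = _mini_config()
    pop = _plants([90.0] * 30 + [95.0] * 10 + [0.0] * 30, cfg)
    high, low = build_bulks(pop, PedsRule.parse(">90"), PedsRule.parse("=0"),
                            10, rng)
    assert all(pop[i].peds > 90 for i in high)


def test_interval_rule_parsing():
    rule = PedsRule.parse("(0,10]")
    assert not rule(0.0) and rule(0.1) and rule(10.0) and not rule(10.1)


def test_overlapping_bulks_share_exactly_the_core(rng):
    cfg = _mini_config()
    pop = _plants([95.0] * 120, cfg)
    bulks = build_overlapping_bulks(pop, PedsRule.parse(">90"),
                                    n_shared=25, n_unique=25, n_bulks=3,
                                    rng=rng)
    assert all(len(b) == 50 for b in bulks)
    core = set(bulks[0]) & set(bulks[1]) & set(bulks[2])
    assert len(core) == 25
    for a in range(3):
        for b in range(a + 1, 3):
            assert set(bulks[a]) & set(bulks[b]) == core


# -- read counts -----------------------------------------------------------

def _founder_pop(cfg, label, n):
    return [Individual(Genome.founder(cfg.chromosomes, label))
            for _ in range(n)]


def test_fixed_bulks_give_extreme_snp_indices(rng):
    cfg = _mini_config(error_rate=0.0, snp_spacing_bp=10_000_000)
    pop = _founder_pop(cfg, TEOSINTE, 10) + _founder_pop(cfg, MAIZE, 10)
    counts = simulate_bulk_counts(pop, np.arange(10), np.arange(10, 20),
                                  cfg, rng)
    assert np.all(counts["HIGH_REF"] == 0)       # all-teosinte: index 1
    assert np.all(counts["LOW_ALT"] == 0)        # all-maize: index 0


def test_half_frequency_bulk_mean_index(rng):
    cfg = _mini_config(error_rate=0.0, snp_spacing_bp=10_000,
                       chromosomes=[ChromosomeSpec("1", 100.0, 100_000_000)])
    f1 = Individual(Genome({
        "1": (Genome.founder(cfg.chromosomes, MAIZE).chromosomes["1"][0],
              Genome.founder(cfg.chromosomes, TEOSINTE).chromosomes["1"][0])}))
    pop = [f1] * 20
    counts = simulate_bulk_counts(pop, np.arange(10), np.arange(10, 20),
                                  cfg, rng)
    idx = counts["HIGH_ALT"] / (counts["HIGH_ALT"] + counts["HIGH_REF"])
    assert len(idx) == 10_000
    assert abs(idx.mean() - 0.5) < 0.01


def test_snp_index_converges_to_bulk_frequency_at_high_depth(rng):
    cfg = _mini_config(error_rate=0.0, depth=1000.0, snp_spacing_bp=1_000_000)
    f1 = Individual(Genome({
        "1": (Genome.founder(cfg.chromosomes, MAIZE).chromosomes["1"][0],
              Genome.founder(cfg.chromosomes, TEOSINTE).chromosomes["1"][0])}))
    pop = [f1] * 20
    counts = simulate_bulk_counts(pop, np.arange(10), np.arange(10, 20),
                                  cfg, rng)
    idx = counts["HIGH_ALT"] / (counts["HIGH_ALT"] + counts["HIGH_REF"])
    assert abs(idx.mean() - 0.5) < 0.005


# -- scheme bookkeeping ----------------------------------------------------

def test_default_scheme_reaches_bc3f2(default_sim):
    names = [h[0] for h in default_sim.history]
    assert names == ["F2", "BC1F1", "BC1F2", "BC2F1", "BC2F2",
                     "BC3F1", "BC3F2"]
    assert default_sim.generation == "BC3F2"
    truth = default_sim.truth()
    assert truth["seed"] == 11
    assert len(truth["qtls"]) == 4 and len(truth["epistasis"]) == 1
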