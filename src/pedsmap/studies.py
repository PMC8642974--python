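"""Replicated planted-truth recovery studies.

Each study simulates many independent mapping populations with a known
planted architecture, runs one analysis arm, and reports the fraction
of replicates in which the planted signal is recovered.  They serve as
operating-characteristic checks of the whole pipeline: the QTL-seq arm
should call a candidate region overlapping a major QTL, and the
interval-mapping arm should place its peak near the QTL with a
variance share close to the planted one, in (nearly) every replicate.
"""

from __future__ import annotations

import numpy as np

from .config import (ChromosomeSpec, EpistasisSpec, QtlSpec, SimConfig,
                     single_qtl_config)
from .linkage import GenotypeMatrix, build_local_map
from .pipeline import _map_cm
from .qtl_scan import IntervalMapping
from .qtlseq import QtlSeq
from .significance import ThresholdCurve, null_delta_distribution
from .simulate import (PedsRule, build_bulks, genotype_markers,
                       simulate_bulk_counts, simulate_f2, simulate_population)

HIGH_RULE = PedsRule.parse(">90")
LOW_RULE = PedsRule.parse("=0")


def qtlseq_recovery_study(n_reps: int, seed: int, *, n_bulk: int = 50,
                          curve: ThresholdCurve | None = None,
                          alpha: float = 0.05) -> dict:
    """QTL-seq arm: does a called region overlap the planted major QTL?

    Each replicate runs the full breeding scheme (BC3F2 with one major
    QTL of transformed-scale heritability ~0.35), builds PEDS>90 /
    PEDS=0 bulks of ``n_bulk`` plants, simulates ~19x read counts and
    calls candidate regions against the Monte-Carlo null band.
    """
    if curve is None:
        curve = null_delta_distribution("F2", n_bulk, n_bulk,
                                        n_reps=10_000, seed=seed)
    hits = 0
    for rep in range(n_reps):
        cfg = single_qtl_config(seed * 10_000 + rep)
        rng = np.random.default_rng(cfg.seed)
        sim = simulate_population(cfg, rng)
        high, low = build_bulks(sim.population, HIGH_RULE, LOW_RULE,
                                n_bulk, rng)
        counts = simulate_bulk_counts(sim.population, high, low, cfg, rng)
        regions = QtlSeq(counts).fit(curve=curve, alpha=alpha).regions_frame()
        q = cfg.qtls[0]
        hits += int(any((r.chrom == q.chrom) and (r.start <= q.pos_bp <= r.end)
                        for r in regions.itertuples()))
    return {"n_reps": n_reps, "hits": hits, "fraction": hits / n_reps}


def icim_add_recovery_study(n_reps: int, seed: int, *, n_individuals: int = 650,
                            cm_tol: float = 10.0, pve_target: float = 35.0,
                            pve_tol: float = 8.0) -> dict:
    """Interval-mapping arm: peak location and PVE of a planted major QTL.

    Each replicate simulates a BC3F2 of ``n_individuals`` plants
    segregating for one QTL with transformed-scale heritability ~0.35,
    builds the local map (marker QC on an unselected F2 sample) and
    scans.  Recovery = chromosome-3 peak within ``cm_tol`` of the
    planted position; the PVE criterion additionally asks the peak PVE
    to be within ``pve_tol`` points of the planted percentage.
    """
    peak_hits = 0
    pve_hits = 0
    add_signs = []
    pves = []
    for rep in range(n_reps):
        cfg = single_qtl_config(seed * 10_000 + rep)
        cfg.n_final = n_individuals
        rng = np.random.default_rng(cfg.seed)
        sim = simulate_population(cfg, rng)
        geno, markers = genotype_markers(sim.population, cfg)
        matrix = GenotypeMatrix(geno, markers)
        qc_geno, qc_markers = genotype_markers(simulate_f2(cfg, 200, rng), cfg)
        # Bonferroni-corrected screen: only serious distortion drops a marker
        alpha = 0.05 / len(markers)
        gmap = build_local_map(matrix, alpha_distortion=alpha,
                               qc_matrix=GenotypeMatrix(qc_geno, qc_markers))
        res = IntervalMapping(sim.phenotypes, matrix, gmap).fit(step_cm=1.0)
        q = cfg.qtls[0]
        true_cm = _map_cm(gmap, {"chrom": q.chrom, "pos_bp": q.pos_bp})
        best = None
        for p in res.qtl.itertuples():
            if p.chrom == q.chrom and (best is None or p.lod > best.lod):
                best = p
        if best is not None and abs(best.cm - true_cm) <= cm_tol:
            peak_hits += 1
            pves.append(float(best.pve))
            add_signs.append(float(np.sign(best.add)))
            if abs(best.pve - pve_target) <= pve_tol:
                pve_hits += 1
    return {
        "n_reps": n_reps, "peak_hits": peak_hits, "pve_hits": pve_hits,
        "peak_fraction": peak_hits / n_reps, "pve_fraction": pve_hits / n_reps,
        "mean_pve": float(np.mean(pves)) if pves else float("nan"),
        "all_add_negative": bool(add_signs and all(s < 0 for s in add_signs)),
    }


def epistasis_test_config(seed: int, aa: float = 0.2) -> SimConfig:
    """Two unlinked loci with a pure additive-by-additive interaction.

    An F2 design (no backcrossing) on two 120 cM chromosomes; both loci
    have zero main effects, so any detected signal is interaction.
    """
    chroms = [ChromosomeSpec("1", 120.0, 180_000_000),
              ChromosomeSpec("2", 120.0, 180_000_000)]
    qtls = [QtlSpec("1", 60.0, 90_000_000, a=0.0, d=0.0, name="epi1"),
            QtlSpec("2", 60.0, 90_000_000, a=0.0, d=0.0, name="epi2")]
    markers = {c: [int(m * 1e6) for m in (30, 60, 90, 120, 150)]
               for c in ("1", "2")}
    return SimConfig(seed=seed, chromosomes=chroms, qtls=qtls,
                     epistasis=[EpistasisSpec(0, 1, aa=aa)],
                     mu=0.5, sigma_e=0.15, n_backcrosses=0, n_final=650,
                     marker_positions=markers)


def icim_epi_recovery_study(n_reps: int, seed: int, *, cm_tol: float = 10.0,
                            lod_threshold: float = 5.0) -> dict:
    """Epistasis arm: recover a planted aa = 0.2 pair with a positive AA."""
    hits = 0
    for rep in range(n_reps):
        cfg = epistasis_test_config(seed * 10_000 + rep)
        sim = simulate_population(cfg)
        geno, markers = genotype_markers(sim.population, cfg)
        matrix = GenotypeMatrix(geno, markers)
        gmap = build_local_map(matrix)
        res = IntervalMapping(sim.phenotypes, matrix, gmap).fit_epistasis(
            step_cm=5.0, lod_threshold=lod_threshold)
        t1 = _map_cm(gmap, {"chrom": "1", "pos_bp": 90_000_000})
        t2 = _map_cm(gmap, {"chrom": "2", "pos_bp": 90_000_000})
        hit = False
        for p in res.pairs.itertuples():
            ends = [(p.chrom1, p.cm1), (p.chrom2, p.cm2)]
            for (c1, m1), (c2, m2) in (ends, ends[::-1]):
                if (c1 == "1" and abs(m1 - t1) <= cm_tol
                        and c2 == "2" and abs(m2 - t2) <= cm_tol
                        and p.aa > 0):
                    hit = True
        hits += int(hit)
    return {"n_reps": n_reps, "hits": hits, "fraction": hits / n_reps}
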