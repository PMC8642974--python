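"""End-to-end pipeline: simulate -> QTL-seq -> linkage -> scans.

Each stage draws randomness from its own substream of the mandatory
run seed (stable per-stage identifiers, so adding a stage does not
shift the randomness of the others), writes its artifacts into the run
directory, and is recorded in a machine-readable manifest with content
hashes.  The final recovery report compares called regions and scan
peaks against the simulator's planted truth.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .config import SimConfig
from .errors import PedsmapError
from .linkage import build_local_map
from .phenotype import summaries_to_frame, summarize_phenotypes
from .qtl_scan import IntervalMapping
from .qtlseq import QtlSeq
from .significance import null_delta_distribution
from .simulate import (PedsRule, build_bulks, genotype_markers,
                       simulate_bulk_counts, simulate_f2, simulate_population)

# stable per-stage substream identifiers; do not renumber
STAGE_IDS = {
    "simulate": 1,
    "bulks": 2,
    "counts": 3,
    "thresholds": 4,
    "qc_f2": 5,
}

#: size of the unselected F2 sample used only for the marker
#: segregation-distortion screen
N_QC_F2 = 200

HIGH_RULE = PedsRule.parse(">90")
LOW_RULE = PedsRule.parse("=0")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, STAGE_IDS[stage]])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(records: list, stage: str, **info) -> None:
    records.append({"stage": stage, **info})


def run_all(config: SimConfig, outdir, *, alpha: float = 0.05,
            n_threshold_reps: int = 10_000, scan_step_cm: float = 1.0,
            epi_step_cm: float = 5.0, make_plots: bool = True) -> Path:
    """Execute the full chain and write every artifact plus a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    files: dict[str, str] = {}

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        files[name] = _sha256(path)
        return path

    stage = "configure"
    try:
        save("config.yaml", config.to_yaml)

        stage = "simulate"
        rng = stage_rng(config.seed, "simulate")
        sim = simulate_population(config, rng)
        peds = sim.phenotypes
        ids = [f"ind{i}" for i in range(len(peds))]
        save("phenotypes.csv",
             lambda p: pio.write_phenotypes_csv(ids, peds, p))
        save("truth.json",
             lambda p: p.write_text(json.dumps(sim.truth(), indent=2)))
        _log(log, stage, generation=sim.generation, n=len(peds),
             history=sim.history)

        stage = "summarize"
        summ = summarize_phenotypes(peds, environment=sim.generation)
        save("summary.tsv",
             lambda p: summaries_to_frame([summ]).to_csv(p, sep="\t",
                                                         index=False))
        _log(log, stage, total=summ.total, ratio=summ.ratio)

        stage = "bulks"
        rng = stage_rng(config.seed, "bulks")
        high_ids, low_ids = build_bulks(sim.population, HIGH_RULE, LOW_RULE,
                                        config.n_bulk, rng)
        save("bulks.json", lambda p: p.write_text(json.dumps(
            {"high": [int(i) for i in high_ids],
             "low": [int(i) for i in low_ids]}, indent=2)))
        _log(log, stage, n_bulk=config.n_bulk)

        stage = "counts"
        rng = stage_rng(config.seed, "counts")
        counts = simulate_bulk_counts(sim.population, high_ids, low_ids,
                                      config, rng)
        save("allele_counts.tsv",
             lambda p: pio.write_allele_counts_tsv(counts, p))
        _log(log, stage, n_snps=len(counts))

        stage = "thresholds"
        curve = null_delta_distribution(
            "F2", config.n_bulk, config.n_bulk, n_reps=n_threshold_reps,
            rng=stage_rng(config.seed, "thresholds"))
        save("thresholds.tsv", lambda p: pio.write_threshold_tsv(curve, p))
        _log(log, stage, n_reps=n_threshold_reps)

        stage = "snp-index"
        model = QtlSeq(counts)
        result = model.fit(curve=curve, alpha=alpha)
        save("snp_index.tsv", lambda p: result.snps.to_csv(
            p, sep="\t", index=False, float_format="%.6g"))
        save("windows.tsv", lambda p: pio.write_windows_tsv(result.windows, p))
        _log(log, stage, **result.filter_counts())

        stage = "call-regions"
        regions = result.regions(alpha)
        save("regions.tsv", lambda p: pio.write_regions_tsv(regions, p))
        save("regions.bed", lambda p: pio.write_regions_bed(regions, p))
        _log(log, stage, n_regions=len(regions), alpha=alpha)

        stage = "build-map"
        genotypes, markers = genotype_markers(sim.population, config)
        from .linkage import GenotypeMatrix
        matrix = GenotypeMatrix(genotypes, markers)
        save("genotypes.csv", lambda p: genotypes.to_csv(p, index_label="id"))
        save("markers.csv", lambda p: markers.to_csv(p, index=False))
        qc_pop = simulate_f2(config, N_QC_F2, stage_rng(config.seed, "qc_f2"))
        qc_geno, qc_markers = genotype_markers(qc_pop, config)
        qc_matrix = GenotypeMatrix(qc_geno, qc_markers)
        # Bonferroni-corrected screen across markers ("serious" distortion)
        gmap = build_local_map(matrix, alpha_distortion=0.05 / len(markers),
                               qc_matrix=qc_matrix)
        save("map.tsv", lambda p: pio.write_map_tsv(gmap, p))
        _log(log, stage, n_markers=len(gmap.table),
             dropped=[d for d in gmap.dropped])

        stage = "scan-qtl"
        im = IntervalMapping(peds, matrix, gmap)
        scan_res = im.fit(step_cm=scan_step_cm)
        save("qtl_scan.tsv", lambda p: scan_res.scan.to_csv(
            p, sep="\t", index=False, float_format="%.6g"))
        save("qtl_peaks.tsv", lambda p: scan_res.qtl.to_csv(
            p, sep="\t", index=False, float_format="%.6g"))
        _log(log, stage, n_peaks=len(scan_res.qtl),
             background=im.background().markers)

        stage = "scan-epi"
        epi_res = im.fit_epistasis(step_cm=epi_step_cm)
        save("epistasis.tsv", lambda p: epi_res.pairs.to_csv(
            p, sep="\t", index=False, float_format="%.6g"))
        _log(log, stage, n_pairs=len(epi_res.pairs))

        stage = "recovery"
        recovery = recovery_report(sim.truth(), result.regions_frame(alpha),
                                   scan_res.qtl, epi_res.pairs, gmap)
        save("recovery.json",
             lambda p: p.write_text(json.dumps(recovery, indent=2)))

        if make_plots:
            stage = "plots"
            from .plotting import save_figure
            (out / "plots").mkdir(exist_ok=True)
            for chrom in {q.chrom for q in config.qtls}:
                ax = result.plot(chrom)
                save_figure(ax, out / "plots" / f"delta_chr{chrom}.png")
            save_figure(scan_res.plot(), out / "plots" / "lod_profile.png")
    except PedsmapError as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    import pedsmap

    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "versions": {"pedsmap": pedsmap.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "stages": log,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return out


def recovery_report(truth: dict, regions: pd.DataFrame, peaks: pd.DataFrame,
                    pairs: pd.DataFrame, gmap, *, cm_slack: float = 15.0,
                    bp_slack: int = 10_000_000) -> dict:
    """Compare called regions / scan peaks / epistatic pairs to the truth.

    A QTL counts as found by QTL-seq when a candidate region on its
    chromosome overlaps its bp position (with ``bp_slack`` tolerance),
    and as found by the scan when a peak on its chromosome lies within
    ``cm_slack`` of its map position.
    """
    qtl_rows = []
    for q in truth["qtls"]:
        in_region = any(
            (r["chrom"] == q["chrom"])
            and (r["start"] - bp_slack <= q["pos_bp"] <= r["end"] + bp_slack)
            for _, r in regions.iterrows())
        near_peak = any(
            (p["chrom"] == q["chrom"]) and abs(p["cm"] - _map_cm(gmap, q)) <= cm_slack
            for _, p in peaks.iterrows())
        qtl_rows.append({**q, "found_qtlseq": bool(in_region),
                         "found_scan": bool(near_peak)})
    epi_rows = []
    for e in truth["epistasis"]:
        q1 = next(q for q in truth["qtls"] if q["name"] == e["qtl1"])
        q2 = next(q for q in truth["qtls"] if q["name"] == e["qtl2"])
        hit = False
        for _, p in pairs.iterrows():
            ends = [(p["chrom1"], p["cm1"]), (p["chrom2"], p["cm2"])]
            for (c1, m1), (c2, m2) in (ends, ends[::-1]):
                if (c1 == q1["chrom"] and abs(m1 - _map_cm(gmap, q1)) <= cm_slack
                        and c2 == q2["chrom"]
                        and abs(m2 - _map_cm(gmap, q2)) <= cm_slack):
                    hit = True
        epi_rows.append({**e, "found_epi_scan": bool(hit)})
    true_chroms = {q["chrom"] for q in truth["qtls"]}
    fp_regions = int(sum(1 for _, r in regions.iterrows()
                         if r["chrom"] not in true_chroms))
    fp_peaks = int(sum(1 for _, p in peaks.iterrows()
                       if p["chrom"] not in true_chroms))
    return {"qtls": qtl_rows, "epistasis": epi_rows,
            "n_regions": int(len(regions)), "n_peaks": int(len(peaks)),
            "n_epi_pairs": int(len(pairs)),
            "false_positive_regions_off_qtl_chroms": fp_regions,
            "false_positive_peaks_off_qtl_chroms": fp_peaks}


def _map_cm(gmap, q: dict) -> float:
    """Planted QTL position on the estimated map (bp interpolation)."""
    sub = gmap.table[gmap.table["chrom"] == q["chrom"]]
    if len(sub) == 0:
        return float("nan")
    bp = sub["bp"].to_numpy(dtype=float)
    cm = sub["cm"].to_numpy(dtype=float)
    return float(np.interp(q["pos_bp"], bp, cm))
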