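"""Readers and writers for the tabular interchange formats.

Conventions: all tables use 1-based bp positions (column POS or bp);
BED exports are 0-based half-open.  Allele counts travel as TSV with
columns CHROM, POS, REF, ALT, HIGH_REF, HIGH_ALT, LOW_REF, LOW_ALT, or
as a VCF whose first two samples (high bulk, low bulk) carry allele
depths in the standard FORMAT/AD field.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError

COUNT_COLUMNS = ["CHROM", "POS", "REF", "ALT",
                 "HIGH_REF", "HIGH_ALT", "LOW_REF", "LOW_ALT"]


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------

def read_allele_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    return df


def write_allele_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_allele_counts_vcf(path, high_sample: str | None = None,
                           low_sample: str | None = None) -> pd.DataFrame:
    """Allele counts from a VCF with per-sample AD (ref,alt) depths.

    By default the first sample is the high bulk and the second the
    low bulk; sample names may be given explicitly.  Multi-allelic
    records are skipped (they are counted by the caller via
    ``drop_multiallelic`` semantics: here they simply do not appear).
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) < 2:
            raise DataError(f"{path}: need at least two samples (high, low)")
        hs = high_sample or samples[0]
        ls = low_sample or samples[1]
        for s in (hs, ls):
            if s not in samples:
                raise DataError(f"{path}: sample {s!r} not present")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            try:
                ad_h = rec.samples[hs]["AD"]
                ad_l = rec.samples[ls]["AD"]
            except KeyError as exc:
                raise DataError(f"{path}: FORMAT lacks AD") from exc
            rows.append({
                "CHROM": rec.chrom, "POS": rec.pos,
                "REF": rec.ref, "ALT": rec.alts[0],
                "HIGH_REF": int(ad_h[0]), "HIGH_ALT": int(ad_h[1]),
                "LOW_REF": int(ad_l[0]), "LOW_ALT": int(ad_l[1]),
            })
    if not rows:
        raise DataError(f"{path}: no biallelic SNP records with AD")
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def read_allele_counts(path) -> pd.DataFrame:
    """Dispatch on extension: .vcf/.vcf.gz or TSV."""
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return read_allele_counts_vcf(path)
    return read_allele_counts_tsv(path)


# ---------------------------------------------------------------------------
# phenotypes and genotypes
# ---------------------------------------------------------------------------

def write_phenotypes_csv(ids, peds, path) -> None:
    pd.DataFrame({"id": ids, "peds_percent": peds}).to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("id", "peds_percent"):
        if c not in df.columns:
            raise DataError(f"{path}: missing column {c!r}")
    return df


def write_genotypes_csv(genotypes: pd.DataFrame, markers: pd.DataFrame,
                        geno_path, marker_path) -> None:
    genotypes.to_csv(geno_path, index_label="id")
    markers.to_csv(marker_path, index=False)


def read_genotypes_csv(geno_path, marker_path):
    from .linkage import GenotypeMatrix

    genotypes = pd.read_csv(geno_path, index_col=0, dtype=str)
    markers = pd.read_csv(marker_path, dtype={"marker": str, "chrom": str})
    return GenotypeMatrix(genotypes.fillna("-"), markers)


# ---------------------------------------------------------------------------
# maps, windows, regions
# ---------------------------------------------------------------------------

def write_map_tsv(gmap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_map_tsv(path):
    from .linkage import GeneticMap

    table = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    need = {"marker", "chrom", "bp", "cm"}
    if not need.issubset(table.columns):
        raise DataError(f"{path}: map table needs columns {sorted(need)}")
    return GeneticMap(table)


def write_windows_tsv(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_threshold_tsv(curve, path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_regions_bed(regions, path) -> None:
    """Candidate regions as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        fh.write("# BED: 0-based half-open candidate regions\n")
        for r in regions:
            start0 = max(int(r.start) - 1, 0)
            end0 = max(int(r.end) - 1, start0 + 1)
            fh.write(f"{r.chrom}\t{start0}\t{end0}\t"
                     f"peak_delta={r.peak_delta:.3f};alpha={r.alpha}\n")


def write_regions_tsv(regions, path) -> None:
    from .significance import regions_to_frame

    regions_to_frame(regions).to_csv(path, sep="\t", index=False,
                                     float_format="%.6g")
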