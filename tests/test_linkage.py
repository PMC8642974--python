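"""Segregation QC, two-point estimation, map functions, map building."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pedsmap import (ConfigError, DataError, GenotypeMatrix, build_local_map,
                     estimate_recfrac, haldane_cm, kosambi_cm, kosambi_r,
                     segregation_chi2)

CODES = np.array(["A", "H", "B"])


def _simulate_pair(r, n, rng):
    """Two-marker F2 genotypes from an explicit gamete model (coupling F1)."""
    g1 = np.empty(n, dtype=object)
    g2 = np.empty(n, dtype=object)
    for i in range(n):
        d1 = d2 = 0
        for _ in range(2):  # two gametes
            a1 = rng.integers(2)
            a2 = a1 ^ (rng.random() < r)
            d1 += a1
            d2 += int(a2)
        g1[i], g2[i] = CODES[d1], CODES[d2]
    return g1, g2


# -- chi-square ------------------------------------------------------------

@pytest.mark.parametrize("counts,chi2,pmin,pmax", [
    ((9, 18, 9), 0.0, 0.999, 1.001),
    ((30, 40, 30), 4.0, 0.13, 0.14),
    ((100, 0, 0), None, 0.0, 1e-20),
])
def test_segregation_chi2_against_1_2_1(counts, chi2, pmin, pmax):
    stat, p = segregation_chi2(counts)
    if chi2 is not None:
        assert stat == pytest.approx(chi2)
    if pmax <= 1e-19:       # extreme distortion: flagged at any alpha
        assert p < pmax
    else:
        assert pmin <= p <= pmax


def test_all_missing_marker_rejected():
    with pytest.raises(DataError):
        segregation_chi2((0, 0, 0))


# -- recombination fraction ------------------------------------------------

def test_identical_markers_estimate_zero(rng):
    g = CODES[rng.integers(0, 3, size=200)]
    r_hat, lod = estimate_recfrac(g, g)
    assert r_hat == 0.0
    assert lod > 10


def test_independent_markers_estimate_half(rng):
    g1, g2 = _simulate_pair(0.5, 1000, rng)
    r_hat, lod = estimate_recfrac(g1, g2)
    assert abs(r_hat - 0.5) < 0.03
    assert lod < 0.5


def test_recfrac_parameter_recovery_at_r_01():
    """Mean estimate over 100 replicates of n=500 recovers r = 0.10."""
    rng = np.random.default_rng(123)
    est = []
    for _ in range(100):
        g1, g2 = _simulate_pair(0.1, 500, rng)
        r_hat, _ = estimate_recfrac(g1, g2)
        est.append(r_hat)
    assert abs(np.mean(est) - 0.10) < 0.01


def test_no_complete_pairs_rejected():
    g1 = np.array(["A", "-", "B"], dtype=object)
    g2 = np.array(["-", "H", "-"], dtype=object)
    with pytest.raises(DataError):
        estimate_recfrac(g1, g2)


# -- map functions ---------------------------------------------------------

def test_kosambi_closed_forms():
    assert kosambi_cm(0.0) == 0.0
    assert kosambi_cm(0.1) == pytest.approx(10.1366, abs=1e-4)
    assert kosambi_r(0.0) == 0.0


def test_kosambi_round_trip_identity():
    for r in (0.01, 0.1, 0.25, 0.4, 0.49):
        assert kosambi_r(kosambi_cm(r)) == pytest.approx(r, abs=1e-10)


def test_kosambi_domain_errors():
    with pytest.raises(ConfigError):
        kosambi_cm(0.5)
    with pytest.raises(ConfigError):
        kosambi_r(-1.0)


@given(st.floats(min_value=1e-6, max_value=0.499))
def test_kosambi_never_exceeds_haldane(r):
    """Kosambi allows partial interference, so its distances are shorter."""
    assert kosambi_cm(r) <= haldane_cm(r) + 1e-12
    if r > 1e-3:
        assert kosambi_cm(r) < haldane_cm(r)


# -- map construction ------------------------------------------------------

def _matrix(columns: dict, meta_rows):
    geno = pd.DataFrame(columns)
    markers = pd.DataFrame(meta_rows)
    return GenotypeMatrix(geno, markers)


def test_two_marker_map_span_close_to_truth(rng):
    g1, g2 = _simulate_pair(0.0906, 500, rng)  # 10 cM under Haldane
    m = _matrix({"m1": g1, "m2": g2},
                [{"marker": "m1", "chrom": "1", "bp": 100},
                 {"marker": "m2", "chrom": "1", "bp": 200}])
    gmap = build_local_map(m, alpha_distortion=1e-6)
    assert 7.0 <= gmap.length_cm("1") <= 13.0
    assert gmap.table["cm"].iloc[0] == 0.0


def test_duplicate_markers_map_zero_distance(rng):
    g = rng.choice(CODES, p=[0.25, 0.5, 0.25], size=300).astype(object)
    m = _matrix({"m1": g, "m2": g.copy()},
                [{"marker": "m1", "chrom": "1", "bp": 100},
                 {"marker": "m2", "chrom": "1", "bp": 200}])
    gmap = build_local_map(m, alpha_distortion=1e-6)
    assert gmap.length_cm("1") == pytest.approx(0.0)


def test_distorted_marker_dropped_others_kept(rng):
    g1, g2 = _simulate_pair(0.1, 300, rng)
    bad = np.array(["A"] * 300, dtype=object)
    m = _matrix({"m1": g1, "bad": bad, "m2": g2},
                [{"marker": "m1", "chrom": "1", "bp": 100},
                 {"marker": "bad", "chrom": "1", "bp": 150},
                 {"marker": "m2", "chrom": "1", "bp": 200}])
    gmap = build_local_map(m)
    assert list(gmap.table["marker"]) == ["m1", "m2"]
    assert any(d.get("marker") == "bad" and d["reason"] == "distorted"
               for d in gmap.dropped)


def test_chromosome_with_single_survivor_dropped(rng):
    g = CODES[rng.integers(0, 3, size=300)]
    m = _matrix({"m1": g},
                [{"marker": "m1", "chrom": "7", "bp": 100}])
    gmap = build_local_map(m)
    assert "7" not in gmap.chromosomes()
    assert any(d.get("chrom") == "7" for d in gmap.dropped)


def test_map_invariant_under_individual_relabelling(rng):
    g1, g2 = _simulate_pair(0.2, 400, rng)
    meta = [{"marker": "m1", "chrom": "1", "bp": 100},
            {"marker": "m2", "chrom": "1", "bp": 200}]
    gmap_a = build_local_map(_matrix({"m1": g1, "m2": g2}, meta))
    perm = rng.permutation(400)
    gmap_b = build_local_map(_matrix({"m1": g1[perm], "m2": g2[perm]}, meta))
    assert np.allclose(gmap_a.table["cm"], gmap_b.table["cm"])


def test_map_length_converges_with_sample_size():
    """Estimation error of the span shrinks from n=200 to n=2000."""
    errs = {}
    for n in (200, 2000):
        rng = np.random.default_rng(7)
        reps = []
        for _ in range(10):
            g1, g2 = _simulate_pair(0.0906, n, rng)
            m = _matrix({"m1": g1, "m2": g2},
                        [{"marker": "m1", "chrom": "1", "bp": 100},
                         {"marker": "m2", "chrom": "1", "bp": 200}])
            reps.append(build_local_map(m, alpha_distortion=1e-6)
                        .length_cm("1"))
        truth = kosambi_cm(0.0906)
        errs[n] = np.mean([abs(x - truth) for x in reps])
    assert errs[2000] < errs[200]


def test_qc_on_separate_f2_sample(rng):
    """Selection-distorted mapping data pass QC via the F2 screen."""
    g1, g2 = _simulate_pair(0.1, 300, rng)
    distorted = np.array(["A"] * 250 + ["H"] * 40 + ["B"] * 10, dtype=object)
    meta = [{"marker": "m1", "chrom": "1", "bp": 100},
            {"marker": "m2", "chrom": "1", "bp": 200}]
    mapping = _matrix({"m1": distorted, "m2": distorted.copy()}, meta)
    qc = _matrix({"m1": g1, "m2": g2}, meta)
    assert len(build_local_map(mapping).table) == 0       # QC on itself: dropped
    gmap = build_local_map(mapping, qc_matrix=qc)
    assert list(gmap.table["marker"]) == ["m1", "m2"]
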