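"""Interval-mapping engine: transforms, conditional probabilities,
stepwise cofactor selection and the two scans."""

import numpy as np
import pandas as pd
import pytest

from pedsmap import (ConfigError, DataError, GeneticMap, GenotypeMatrix,
                     IntervalMapping, cube_root_transform, kosambi_r,
                     qtl_genotype_probs, stepwise_marker_selection)
from pedsmap.qtl_scan import (StepwiseFit, _lod_fit, conditional_prob_table,
                              icim_add_scan, marker_scores)

CODES = np.array(["A", "H", "B"])


# -- transform -------------------------------------------------------------

@pytest.mark.parametrize("peds,expected", [
    (0.0, 0.0), (100.0, 4.6416), (12.5, 2.3208),
])
def test_cube_root_values(peds, expected):
    assert cube_root_transform(peds) == pytest.approx(expected, abs=1e-4)


def test_cube_root_rejects_out_of_range():
    with pytest.raises(DataError):
        cube_root_transform(101.0)
    with pytest.raises(DataError):
        cube_root_transform(-0.1)


def test_cube_root_monotone():
    vals = cube_root_transform(np.linspace(0, 100, 50))
    assert np.all(np.diff(vals) > 0)


# -- conditional QTL genotype probabilities --------------------------------

def test_probs_at_typed_marker_are_degenerate():
    assert qtl_genotype_probs("A", "A", 0.0, 0.1) == pytest.approx((1, 0, 0))
    assert qtl_genotype_probs("B", "B", 0.0, 0.1) == pytest.approx((0, 0, 1))


def test_probs_with_both_flanks_missing_are_f2_prior():
    assert qtl_genotype_probs("-", "-", 0.1, 0.1) == pytest.approx(
        (0.25, 0.5, 0.25))


def test_probs_midpoint_double_het():
    r = float(kosambi_r(10.0))
    p = qtl_genotype_probs("H", "H", r, r)
    assert sum(p) == pytest.approx(1.0)
    assert p[1] == max(p)                     # heterozygote is the mode


def test_inconsistent_flank_recombination_rejected():
    with pytest.raises(ConfigError):
        qtl_genotype_probs("A", "A", 0.1, 0.1, r_flank=0.3)
    with pytest.raises(ConfigError):
        qtl_genotype_probs("A", "A", 0.6, 0.1)


def _oracle_conditional(r1, r2):
    """Independent enumeration of P(Q | left, right) over gamete triples."""
    haps = []
    for a in (0, 1):
        for q in (0, 1):
            for b in (0, 1):
                p = 0.5 * ((1 - r1) if a == q else r1) * \
                    ((1 - r2) if q == b else r2)
                haps.append(((a, q, b), p))
    joint = np.zeros((3, 3, 3))
    for (a1, q1, b1), p1 in haps:
        for (a2, q2, b2), p2 in haps:
            joint[a1 + a2, q1 + q2, b1 + b2] += p1 * p2
    return joint


@pytest.mark.parametrize("r1,r2", [(0.05, 0.05), (0.1, 0.3), (0.0, 0.2),
                                   (0.25, 0.25)])
def test_conditional_table_matches_enumeration_oracle(r1, r2):
    joint = _oracle_conditional(r1, r2)
    table = conditional_prob_table(r1, r2)
    for gl in range(3):
        for gr in range(3):
            cell = joint[gl, :, gr]
            if cell.sum() == 0:
                continue
            assert table[gl, gr] == pytest.approx(cell / cell.sum())
    for gl in range(3):
        marg = joint[gl].sum(axis=1)
        assert table[gl, 3] == pytest.approx(marg / marg.sum())


# -- fixtures --------------------------------------------------------------

def _f2_matrix(rng, n=300, markers=("m1", "m2", "m3"), chrom="1"):
    cols = {m: rng.choice(CODES, p=[0.25, 0.5, 0.25], size=n).astype(object)
            for m in markers}
    meta = [{"marker": m, "chrom": chrom, "bp": 100 * (i + 1)}
            for i, m in enumerate(markers)]
    return GenotypeMatrix(pd.DataFrame(cols), pd.DataFrame(meta))


def _map_for(matrix, cm_step=10.0):
    rows = []
    for chrom in dict.fromkeys(matrix.markers["chrom"]):
        sub = matrix.markers[matrix.markers["chrom"] == chrom]
        for i, (_, r) in enumerate(sub.iterrows()):
            rows.append({"marker": r["marker"], "chrom": chrom,
                         "bp": r["bp"], "cm": i * cm_step})
    return GeneticMap(pd.DataFrame(rows))


# -- stepwise selection ----------------------------------------------------

def test_stepwise_selects_the_causal_marker(rng):
    matrix = _f2_matrix(rng, n=300)
    x, _ = marker_scores(matrix, "m2")
    y = 1.0 + 0.5 * x + rng.normal(0, 0.01, 300)
    fit = stepwise_marker_selection(y, matrix)
    assert fit.markers == ["m2"]
    a, d = fit.coefficients["m2"]
    assert a == pytest.approx(0.5, abs=0.01)


def test_stepwise_duplicated_marker_tie_break(rng):
    n = 300
    g = rng.choice(CODES, p=[0.25, 0.5, 0.25], size=n).astype(object)
    cols = {"dupA": g, "dupB": g.copy()}
    meta = [{"marker": "dupA", "chrom": "1", "bp": 100},
            {"marker": "dupB", "chrom": "1", "bp": 200}]
    matrix = GenotypeMatrix(pd.DataFrame(cols), pd.DataFrame(meta))
    x, _ = marker_scores(matrix, "dupA")
    y = 0.4 * x + rng.normal(0, 0.05, n)
    fit = stepwise_marker_selection(y, matrix)
    assert fit.markers == ["dupA"]           # first in (chrom, bp) order


def test_stepwise_null_false_selection_rate():
    """With pure-noise phenotypes the entry rate stays near p_in."""
    n_reps, n, n_markers, p_in = 200, 100, 20, 0.01
    rng = np.random.default_rng(42)
    matrix = _f2_matrix(rng, n=n, markers=tuple(f"m{i}" for i in range(n_markers)))
    any_selected = 0
    for _ in range(n_reps):
        y = rng.normal(size=n)
        fit = stepwise_marker_selection(y, matrix, p_in=p_in, p_out=0.02)
        any_selected += bool(fit.markers)
    expected = 1 - (1 - p_in) ** n_markers   # ~0.18 family-wise
    se = np.sqrt(expected * (1 - expected) / n_reps)
    assert abs(any_selected / n_reps - expected) < 4 * se + 0.02


def test_stepwise_rejects_too_small_sample(rng):
    matrix = _f2_matrix(rng, n=30, markers=tuple(f"m{i}" for i in range(20)))
    with pytest.raises(DataError, match="larger population"):
        stepwise_marker_selection(rng.normal(size=30), matrix)


# -- single-QTL scan -------------------------------------------------------

def test_scan_at_marker_equals_direct_regression(rng):
    """At a typed marker with empty background the scan LOD is the
    plain two-covariate regression LOD."""
    matrix = _f2_matrix(rng, n=250)
    gmap = _map_for(matrix)
    x, z = marker_scores(matrix, "m2")
    y = 0.3 * x + 0.2 * z + rng.normal(0, 0.5, 250)
    empty_bg = StepwiseFit([], {}, 0.0, 0.01, 0.02)
    scan, _ = icim_add_scan(y, gmap, matrix, step_cm=10.0,
                            background=empty_bg)
    n = len(y)
    X0 = np.ones((n, 1))
    X1 = np.column_stack([np.ones(n), x, z])
    rss0 = float(np.sum((y - y.mean()) ** 2))
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss1 = float(np.sum((y - X1 @ beta) ** 2))
    lod_direct = 0.5 * n * np.log10(rss0 / rss1)
    at_marker = scan[(scan["cm"] == 10.0)].iloc[0]
    assert at_marker["lod"] == pytest.approx(lod_direct, rel=1e-9)
    assert at_marker["add"] == pytest.approx(beta[1], rel=1e-9)
    assert at_marker["dom"] == pytest.approx(beta[2], rel=1e-9)


def test_scan_equals_regression_oracle_at_every_marker(rng):
    matrix = _f2_matrix(rng, n=200, markers=("a", "b", "c", "d", "e"))
    gmap = _map_for(matrix)
    y = rng.normal(size=200)
    empty_bg = StepwiseFit([], {}, 0.0, 0.01, 0.02)
    scan, _ = icim_add_scan(y, gmap, matrix, step_cm=10.0,
                            background=empty_bg)
    n = len(y)
    for i, m in enumerate(("a", "b", "c", "d", "e")):
        x, z = marker_scores(matrix, m)
        X1 = np.column_stack([np.ones(n), x, z])
        beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
        rss1 = float(np.sum((y - X1 @ beta) ** 2))
        rss0 = float(np.sum((y - y.mean()) ** 2))
        lod = 0.5 * n * np.log10(rss0 / rss1)
        assert scan[scan["cm"] == 10.0 * i].iloc[0]["lod"] == \
            pytest.approx(lod, rel=1e-9)


def test_lod_invariant_under_affine_phenotype_transform(rng):
    matrix = _f2_matrix(rng, n=200)
    gmap = _map_for(matrix)
    y = rng.normal(size=200)
    bg = StepwiseFit([], {}, 0.0, 0.01, 0.02)
    scan_a, _ = icim_add_scan(y, gmap, matrix, background=bg)
    scan_b, _ = icim_add_scan(3.0 * y + 5.0, gmap, matrix, background=bg)
    assert np.allclose(scan_a["lod"], scan_b["lod"])


def test_null_scan_rarely_exceeds_lod_3(rng):
    """No-QTL phenotypes: genome-wide max LOD < 3 in most replicates."""
    matrix = _f2_matrix(rng, n=200, markers=("a", "b", "c", "d"))
    gmap = _map_for(matrix)
    bg = StepwiseFit([], {}, 0.0, 0.01, 0.02)
    ok = 0
    n_reps = 20
    for _ in range(n_reps):
        y = rng.normal(size=200)
        scan, _ = icim_add_scan(y, gmap, matrix, step_cm=2.0, background=bg)
        ok += scan["lod"].max() < 3.0
    assert ok >= int(0.85 * n_reps)


def test_scan_results_deterministic(rng):
    matrix = _f2_matrix(rng, n=200)
    gmap = _map_for(matrix)
    x, z = marker_scores(matrix, "m2")
    peds = np.clip(50 + 30 * x + rng.normal(0, 10, 200), 0, 100)
    model = IntervalMapping(peds, matrix, gmap)
    res1 = model.fit()
    res2 = IntervalMapping(peds, matrix, gmap).fit()
    pd.testing.assert_frame_equal(res1.scan, res2.scan)
    assert isinstance(res1.summary(), str)


# -- epistasis scan --------------------------------------------------------

def test_epistasis_lod_symmetric_under_locus_swap(rng):
    n = 300
    x1 = rng.choice([-1.0, 0.0, 1.0], p=[0.25, 0.5, 0.25], size=n)
    x2 = rng.choice([-1.0, 0.0, 1.0], p=[0.25, 0.5, 0.25], size=n)
    z1 = (x1 == 0).astype(float)
    z2 = (x2 == 0).astype(float)
    y = 0.3 * x1 * x2 + rng.normal(0, 0.3, n)
    lod_a, beta_a, _, _ = _lod_fit(y, [x1 * x2, x1 * z2, z1 * x2, z1 * z2],
                                   null_regressors=[x1, z1, x2, z2])
    lod_b, beta_b, _, _ = _lod_fit(y, [x2 * x1, x2 * z1, z2 * x1, z2 * z1],
                                   null_regressors=[x2, z2, x1, z1])
    assert lod_a == pytest.approx(lod_b, rel=1e-9)
    assert beta_a[5] == pytest.approx(beta_b[5], rel=1e-9)  # the aa term


def test_epistasis_null_rarely_exceeds_lod_5(rng):
    matrix = _f2_matrix(rng, n=200, markers=("a", "b", "c", "d"))
    gmap = _map_for(matrix)
    bg = StepwiseFit([], {}, 0.0, 0.01, 0.02)
    from pedsmap.qtl_scan import icim_epi_scan
    hits = 0
    n_reps = 15
    for _ in range(n_reps):
        y = rng.normal(size=200)
        pairs = icim_epi_scan(y, gmap, matrix, step_cm=10.0, background=bg,
                              lod_threshold=5.0)
        hits += len(pairs) > 0
    assert hits <= int(0.2 * n_reps) + 1


def test_same_chromosome_pairs_respect_minimum_separation(rng):
    matrix = _f2_matrix(rng, n=200, markers=("a", "b", "c"))
    gmap = _map_for(matrix)
    bg = StepwiseFit([], {}, 0.0, 0.01, 0.02)
    from pedsmap.qtl_scan import icim_epi_scan
    y = rng.normal(size=200)
    pairs = icim_epi_scan(y, gmap, matrix, step_cm=5.0, background=bg,
                          lod_threshold=0.0, prune=False)
    same = pairs[pairs["chrom1"] == pairs["chrom2"]]
    assert (np.abs(same["cm1"] - same["cm2"]) >= 5.0 - 1e-9).all()
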