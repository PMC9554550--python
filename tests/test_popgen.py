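import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from poolclover.datatypes import PairwiseStatMatrix
from poolclover.popgen import (
    expected_heterozygosity,
    group_summary,
    haversine_matrix,
    mantel_ibd,
    nei_standard_distance,
    pairwise_fst,
    tajima_constants,
    tajimas_d,
)
from poolclover.counts_io import to_frequencies
from poolclover.synthetic import simulate_clusters

from conftest import make_accessions, make_afm, make_rcm, wc_theta


# ---------------------------------------------------------------------------
# expected heterozygosity

@pytest.mark.parametrize("freqs,expected", [
    ([0.5, 0.5, 0.5], 0.5),                    # bi-allelic maximum
    ([0.0, 1.0, 0.0], 0.0),                    # fixed everywhere
    ([0.1, 0.3], (0.18 + 0.42) / 2),           # hand arithmetic
])
def test_expected_heterozygosity_values(freqs, expected):
    out = expected_heterozygosity(make_afm([freqs]))
    assert out["H_S"].iloc[0] == pytest.approx(expected)


def test_expected_heterozygosity_all_missing_flagged():
    afm = make_afm([[np.nan, np.nan], [0.5, 0.5]])
    with pytest.warns(UserWarning, match="all loci missing"):
        out = expected_heterozygosity(afm)
    assert math.isnan(out["H_S"].iloc[0]) and out["n_loci"].iloc[0] == 0


def test_finite_pool_correction_scales_by_n_over_n_minus_1():
    out = expected_heterozygosity(make_afm([[0.5]], pool_n=10),
                                  finite_pool_correction=True)
    assert out["H_S"].iloc[0] == pytest.approx(0.5 * 20 / 19)


# ---------------------------------------------------------------------------
# Nei's standard distance

def test_nei_identity_and_symmetry(rng):
    f = rng.uniform(0.05, 0.95, size=(3, 30))
    f[1] = f[0]
    mat = nei_standard_distance(make_afm(f))
    assert mat.values[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(mat.values, mat.values.T)
    assert np.all(np.diag(mat.values) == 0)
    assert np.all(mat.values[np.isfinite(mat.values)] >= 0)


def test_nei_single_locus_hand_value():
    # X fixed p=0 (x=(1,0)), Y p=0.5: J_X=1, J_Y=0.5, J_XY=0.5
    mat = nei_standard_distance(make_afm([[0.0], [0.5]]))
    assert mat.values[0, 1] == pytest.approx(-math.log(0.5 / math.sqrt(0.5)), abs=1e-9)


def test_nei_opposite_fixation_inf_sentinel():
    with pytest.warns(UserWarning, match="opposite alleles"):
        mat = nei_standard_distance(make_afm([[0.0], [1.0]]))
    assert math.isinf(mat.values[0, 1])


# ---------------------------------------------------------------------------
# pairwise F_ST

def test_fst_fixed_opposite_alleles_is_one():
    counts = np.array([[(200, 0)], [(0, 200)]])
    mat, recs = pairwise_fst(make_rcm(counts))
    assert mat.values[0, 1] == pytest.approx(1.0)
    assert recs[0].fst == pytest.approx(1.0)


def test_fst_uninformative_locus_excluded():
    # locus 2 monomorphic same allele in both pools: 1 - Q2 = 0
    counts = np.array([[(150, 50), (0, 200)], [(50, 150), (0, 200)]])
    mat, recs = pairwise_fst(make_rcm(counts))
    assert [r.locus_id for r in recs] == ["L0001"]
    assert np.isfinite(mat.values[0, 1])


def test_fst_low_coverage_locus_excluded_per_pair():
    counts = np.array([[(1, 0), (60, 40)], [(100, 100), (40, 60)]])
    _, recs = pairwise_fst(make_rcm(counts))
    assert [r.locus_id for r in recs] == ["L0002"]


def test_fst_infinite_depth_matches_weir_cockerham(rng):
    # with exact pool frequencies as counts, the identity-based pool
    # estimator must agree with the Weir-Cockerham ANOVA oracle
    n = 20
    k = rng.binomial(n, rng.uniform(0.1, 0.9, size=(1, 80)), size=(5, 80))
    counts = np.stack([(n - k) * 50000, k * 50000], axis=-1)
    mat, _ = pairwise_fst(make_rcm(counts), keep_per_locus=False)
    for i in range(5):
        for j in range(i + 1, 5):
            oracle = wc_theta(k[[i, j]], np.array([n, n]))
            assert mat.values[i, j] == pytest.approx(oracle, abs=1e-3)


def test_fst_negative_values_preserved():
    # two pools drawn from one panmictic population: estimates scatter
    # around zero and negative multilocus values must not be truncated
    _, rcm = simulate_clusters(1, 12, 400, f_within=1e-4, seed=5)
    mat, _ = pairwise_fst(rcm, keep_per_locus=False)
    tri = mat.lower_triangle()
    assert tri.min() < 0
    assert abs(tri.mean()) < 0.02


# ---------------------------------------------------------------------------
# Tajima's D

@pytest.mark.parametrize("n", [10, 20, 40])
def test_tajima_constants_match_exact_arithmetic(n):
    # independent oracle: exact rational arithmetic of the 1989 constants
    a1 = Fraction(0)
    a2 = Fraction(0)
    for i in range(1, n):
        a1 += Fraction(1, i)
        a2 += Fraction(1, i * i)
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    c = tajima_constants(n)
    for name, exact in [("a1", a1), ("a2", a2), ("b1", b1), ("b2", b2),
                        ("c1", c1), ("c2", c2), ("e1", e1), ("e2", e2)]:
        assert getattr(c, name) == pytest.approx(float(exact), abs=1e-10), name


def test_tajimas_d_singleton_excess_is_negative():
    # every segregating locus a singleton (k=1 of n=20): rare-allele excess
    afm = make_afm([np.full(50, 1 / 20)], pool_n=10)
    out = tajimas_d(afm)
    assert out["D"].iloc[0] < 0
    assert out["S"].iloc[0] == 50


def test_tajimas_d_too_few_segregating_sites():
    afm = make_afm([[0.0, 1.0, 0.5]], pool_n=10)
    with pytest.warns(UserWarning, match="segregating"):
        out = tajimas_d(afm)
    assert math.isnan(out["D"].iloc[0])


def test_tajimas_d_neutral_sfs_centered(rng):
    # frequencies drawn from the neutral spectrum p(k) ~ 1/k are the
    # regime where pi-hat and Watterson's theta agree in expectation
    n = 20
    kvals = np.arange(1, n)
    probs = (1 / kvals) / (1 / kvals).sum()
    ds = []
    for _ in range(100):
        k = rng.choice(kvals, p=probs, size=200)
        ds.append(tajimas_d(make_afm([k / n], pool_n=10))["D"].iloc[0])
    assert -0.3 < np.mean(ds) < 0.3


# ---------------------------------------------------------------------------
# Mantel isolation by distance

def _line_coords(n):
    return np.column_stack([np.linspace(50, 60, n), np.full(n, 10.0)])


def test_mantel_perfect_monotone():
    coords = _line_coords(8)
    geo = haversine_matrix(coords[:, 0], coords[:, 1])
    gen = PairwiseStatMatrix(accession_ids=[f"a{i}" for i in range(8)],
                             values=0.001 * geo, statistic="nei_D")
    r, p = mantel_ibd(gen, coords, n_perm=99, seed=0)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(1 / 100)


def test_mantel_r_matches_skbio(rng):
    from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel
    n = 10
    coords = np.column_stack([rng.uniform(55, 65, n), rng.uniform(5, 20, n)])
    v = rng.uniform(0.01, 0.2, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    ids = [f"a{i}" for i in range(n)]
    gen = PairwiseStatMatrix(accession_ids=ids, values=v, statistic="nei_D")
    r, _ = mantel_ibd(gen, coords, n_perm=99, seed=0)
    geo = haversine_matrix(coords[:, 0], coords[:, 1])
    r_skbio, _, _ = skbio_mantel(DistanceMatrix(v, ids), DistanceMatrix(geo, ids),
                                 permutations=0)
    assert r == pytest.approx(r_skbio, abs=1e-12)


def test_mantel_duplicate_coordinates_handled():
    coords = _line_coords(6)
    coords[1] = coords[0]  # identical sites: zero geographic distance
    rng = np.random.default_rng(4)
    v = rng.uniform(0.01, 0.2, size=(6, 6))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    gen = PairwiseStatMatrix(accession_ids=[f"a{i}" for i in range(6)],
                             values=v, statistic="nei_D")
    r, p = mantel_ibd(gen, coords, n_perm=99, seed=1)
    assert np.isfinite(r) and 0 < p <= 1


def test_mantel_constant_matrix_errors():
    gen = PairwiseStatMatrix(accession_ids=list("abcd"),
                             values=np.ones((4, 4)) - np.eye(4), statistic="nei_D")
    with pytest.raises(ValueError, match="constant"):
        mantel_ibd(gen, _line_coords(4), n_perm=99, seed=0)


def test_mantel_null_p_uniform(rng):
    # null calibration: genetic distances independent of geography give
    # a p-value that is approximately Uniform(0,1) over replicates
    n = 12
    ids = [f"a{i}" for i in range(n)]
    coords = np.column_stack([rng.uniform(55, 65, n), rng.uniform(5, 20, n)])
    ps = []
    for rep in range(500):
        v = rng.uniform(0.0, 1.0, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        gen = PairwiseStatMatrix(accession_ids=ids, values=v, statistic="nei_D")
        _, p = mantel_ibd(gen, coords, n_perm=99, seed=rep)
        ps.append(p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# group summaries

def _group_inputs(freqs, types):
    accs = make_accessions(len(types))
    accs = [type(a)(accession_id=a.accession_id, type_group=t,
                    origin_group="Synthetic", pool_n_individuals=10)
            for a, t in zip(accs, types)]
    afm = make_afm(freqs, accessions=accs)
    hs = expected_heterozygosity(afm)
    d = tajimas_d(afm, min_segregating=1)
    nei = nei_standard_distance(afm)
    fst_vals = np.zeros_like(nei.values)
    fst = PairwiseStatMatrix(accession_ids=afm.accession_ids, values=fst_vals,
                             statistic="fst")
    return hs, d, nei, fst, accs


def test_group_summary_singleton_has_no_pairwise_stats(rng):
    f = rng.uniform(0.1, 0.9, size=(3, 20))
    hs, d, nei, fst, accs = _group_inputs(f, ["WildPopulation", "WildPopulation", "Cultivar"])
    out = group_summary(hs, d, nei, fst, accs, group_by="type")
    assert math.isnan(out.loc["Cultivar", "nei_D"])
    assert math.isnan(out.loc["Cultivar", "fst"])
    assert np.isfinite(out.loc["WildPopulation", "nei_D"])
    # cross-tab percentages of the other grouping sum to 100 per group
    pct = out.filter(like="pct_").to_numpy().sum(axis=1)
    np.testing.assert_allclose(pct, 100.0)


def test_group_summary_identical_accessions_zero_nei(rng):
    f = np.tile(rng.uniform(0.1, 0.9, size=20), (2, 1))
    hs, d, nei, fst, accs = _group_inputs(f, ["Landrace", "Landrace"])
    out = group_summary(hs, d, nei, fst, accs, group_by="type")
    assert out.loc["Landrace", "nei_D"] == pytest.approx(0.0, abs=1e-12)


def test_group_summary_orders_planted_differentiation():
    # group with stronger drift has the larger mean within-group F_ST
    _, rcm_hi = simulate_clusters(1, 6, 500, f_within=0.1, seed=2)
    _, rcm_lo = simulate_clusters(1, 6, 500, f_within=0.01, seed=3)
    import poolclover.datatypes as dt
    accs = []
    for i, a in enumerate(rcm_hi.accessions + rcm_lo.accessions):
        accs.append(dt.AccessionMetadata(accession_id=f"p{i}",
                                         type_group="WildPopulation" if i < 6 else "Cultivar"))
    counts = np.concatenate([rcm_hi.counts, rcm_lo.counts], axis=0)
    rcm = dt.ReadCountMatrix(accessions=accs, loci=rcm_hi.loci, counts=counts)
    afm = to_frequencies(rcm)
    fst, _ = pairwise_fst(rcm, keep_per_locus=False)
    hs = expected_heterozygosity(afm)
    d = tajimas_d(afm)
    nei = nei_standard_distance(afm)
    out = group_summary(hs, d, nei, fst, accs, group_by="type")
    assert out.loc["WildPopulation", "fst"] > out.loc["Cultivar", "fst"]


def test_group_summary_unknown_grouping_errors(rng):
    f = rng.uniform(0.1, 0.9, size=(2, 5))
    hs, d, nei, fst, accs = _group_inputs(f, ["Cultivar", "Cultivar"])
    with pytest.raises(ValueError, match="group_by"):
        group_summary(hs, d, nei, fst, accs, group_by="flavour")
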