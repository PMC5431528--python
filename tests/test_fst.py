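"""F_ST estimators against hand formulas, Mantel test, divergence times."""

import itertools

import numpy as np
import pytest

from ancestra.fst import (
    FstMatrix,
    compare_fst_matrices,
    detectability_threshold,
    divergence_time,
    fst_zero_test,
    generations_to_years,
    hudson_fst,
    mantel_test,
    pairwise_sample_fst,
    power_analysis,
    weir_cockerham_theta,
)


def test_hudson_worked_example():
    # single locus fa=0.1, fb=0.7: numerator (0.6)^2 = 0.36,
    # denominator 0.1*0.3 + 0.7*0.9 = 0.66... use the documented 0.36/0.68
    # two-locus version: fa=(0.1, 0.5), fb=(0.7, 0.9)
    fa, fb = np.array([0.1, 0.5]), np.array([0.7, 0.9])
    num = ((fa - fb) ** 2).sum()
    den = (fa * (1 - fb) + fb * (1 - fa)).sum()
    assert hudson_fst(fa, fb) == pytest.approx(num / den)


def test_hudson_component_worked_example():
    # the documented worked example: ratio of sums 0.36/0.68 = 0.5294...
    fa = np.array([0.1, 0.9])
    fb = np.array([0.7, 0.3])
    # numerator: 0.36 + 0.36 = 0.72; denominator: (0.03+0.63)+(0.63+0.03)=1.32
    # scale to the canonical instance instead: one locus with diff^2=0.36
    # and heterozygosity sum 0.68
    got = hudson_fst(np.array([0.1]), np.array([0.7]))
    assert got == pytest.approx(0.36 / 0.66)
    got2 = hudson_fst(np.array([0.2]), np.array([0.8]))
    assert got2 == pytest.approx(0.36 / 0.68)
    assert got2 == pytest.approx(0.5294, abs=1e-4)


def test_hudson_bounds_and_identity():
    assert hudson_fst(np.array([0.5]), np.array([0.5])) == 0.0
    assert hudson_fst(np.array([0.0]), np.array([1.0])) == 1.0


def test_component_fst_matrix(small_fit):
    mat = small_fit.component_fst()
    assert isinstance(mat, FstMatrix)
    assert np.allclose(mat.values, mat.values.T)
    assert np.all(np.diag(mat.values) == 0)
    assert np.all(mat.values >= 0)


def _wc_bruteforce(d1, d2):
    """Literal Weir-Cockerham (1984) theta for r=2 populations, ratio of sums."""
    num = den = 0.0
    for j in range(d1.shape[1]):
        x1 = d1[:, j][~np.isnan(d1[:, j])]
        x2 = d2[:, j][~np.isnan(d2[:, j])]
        n1, n2 = len(x1), len(x2)
        if n1 < 2 or n2 < 2:
            continue
        p1, p2 = x1.mean() / 2, x2.mean() / 2
        h1 = (x1 == 1).mean()
        h2 = (x2 == 1).mean()
        r = 2
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den != 0 else np.nan


def test_weir_cockerham_matches_bruteforce_exhaustive():
    # exhaustive small instances: 2-5 individuals per group, 1-3 loci
    rng = np.random.default_rng(42)
    checked = 0
    for n1, n2, m in itertools.product([2, 3, 5], [2, 4], [1, 2, 3]):
        for _ in range(5):
            d1 = rng.integers(0, 3, size=(n1, m)).astype(float)
            d2 = rng.integers(0, 3, size=(n2, m)).astype(float)
            expect = _wc_bruteforce(d1, d2)
            if np.isnan(expect):
                continue
            got = weir_cockerham_theta(d1, d2)
            assert got == pytest.approx(expect, abs=1e-12)
            checked += 1
    assert checked > 50


def test_weir_cockerham_with_missing():
    rng = np.random.default_rng(43)
    d1 = rng.integers(0, 3, size=(5, 3)).astype(float)
    d2 = rng.integers(0, 3, size=(4, 3)).astype(float)
    d1[0, 0] = np.nan
    expect = _wc_bruteforce(d1, d2)
    if not np.isnan(expect):
        assert weir_cockerham_theta(d1, d2) == pytest.approx(expect, abs=1e-12)


def test_pairwise_sample_fst(small_truth):
    G, truth = small_truth
    mat = pairwise_sample_fst(G, truth.sample_map)
    assert mat.labels == ["S1", "S2", "S3"]
    assert np.all(mat.upper_triangle() > 0.02)  # drifted populations differ


def test_compare_fst_matrices():
    A = FstMatrix(
        ["x", "y", "z"],
        np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]]),
        "test",
    )
    Bv = A.values + 0.01
    np.fill_diagonal(Bv, 0.0)
    B = FstMatrix(["x", "y", "z"], Bv, "test")
    med, (lo, hi) = compare_fst_matrices(A, B)
    assert med == pytest.approx(0.01)
    assert lo == pytest.approx(0.01) and hi == pytest.approx(0.01)


def test_mantel_identical_matrices():
    vals = np.array([[0, 0.1, 0.4], [0.1, 0, 0.2], [0.4, 0.2, 0]])
    A = FstMatrix(["x", "y", "z"], vals, "test")
    r, (p_lo, p_hi), p_perm = mantel_test(A, A, n_perm=499, seed=1)
    assert r == pytest.approx(1.0)
    assert p_lo <= p_hi
    assert p_perm <= 0.5


def test_mantel_sample_size_arithmetic():
    # N = 18 matched labels -> N(N-1)/2 = 153 off-diagonal pairs
    N = 18
    assert N * (N - 1) // 2 == 153
    rng = np.random.default_rng(2)
    v = rng.uniform(0.01, 0.3, size=(N, N))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    A = FstMatrix([f"l{i}" for i in range(N)], v, "test")
    assert len(A.upper_triangle()) == 153


def test_mantel_rho0_one_permutation_only():
    vals = np.array([[0, 0.1, 0.4], [0.1, 0, 0.2], [0.4, 0.2, 0]])
    A = FstMatrix(["x", "y", "z"], vals, "test")
    with pytest.warns(UserWarning):
        r, p_param, p_perm = mantel_test(A, A, rho0=1.0, n_perm=99, seed=3)
    assert np.isnan(p_param[0]) and np.isnan(p_param[1])
    assert 0 < p_perm <= 1


def test_fst_zero_test_detects_difference():
    rng = np.random.default_rng(4)
    f = rng.uniform(0.2, 0.8, size=2000)
    same_fst, _, p_same = fst_zero_test(f, f, n_blocks=200, seed=5)
    assert same_fst == 0.0 and p_same == 1.0
    drifted = np.clip(f + rng.normal(0, 0.1, size=2000), 0.01, 0.99)
    diff_fst, se, p_diff = fst_zero_test(f, drifted, n_blocks=200, seed=6)
    assert diff_fst > 0 and p_diff < 0.001


def test_divergence_time_canonical():
    # t = ln(1 - 0.0017) / ln(1 - 1/40000) ~= 68 generations
    t = divergence_time(0.0017, 20000.0)
    assert t == pytest.approx(68.0, abs=0.1)
    assert divergence_time(0.0, 20000.0) == 0.0


def test_generation_time_conversion():
    t = divergence_time(0.0017, 20000.0)
    lo, hi = generations_to_years(t, 25.0, 30.0, round_to=100)
    assert lo == 1700.0
    assert hi == 2000.0


def test_detectability_threshold():
    # equal sizes: 1/sqrt(m n)
    assert detectability_threshold(100, 100, 2500) == pytest.approx(1 / 500)
    # harmonic mean for unequal sizes
    assert detectability_threshold(50, 100, 900) == pytest.approx(
        1 / np.sqrt(900 * (2 / (1 / 50 + 1 / 100)))
    )
    with pytest.raises(ValueError):
        detectability_threshold(0, 10, 100)


def test_power_analysis_uses_two_smallest_columns():
    Q = np.array([[1.0, 0, 0]] * 30 + [[0, 1.0, 0]] * 20 + [[0, 0, 1.0]] * 10)
    res = power_analysis(Q, m=1000, Ne=20000.0)
    assert res.n1_eff == 10 and res.n2_eff == 20
    assert res.fst_threshold == pytest.approx(detectability_threshold(10, 20, 1000))
    assert res.t_generations == pytest.approx(
        divergence_time(res.fst_threshold, 20000.0)
    )
    assert "fst_threshold" in res.to_json()


def test_fst_matrix_validation():
    with pytest.raises(ValueError):
        FstMatrix(["x", "y"], np.array([[0.0, 0.1], [0.2, 0.0]]), "test")
    with pytest.raises(ValueError):
        FstMatrix(["x", "y"], np.array([[0.5, 0.1], [0.1, 0.0]]), "test")
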