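import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

import pprscope as pp


def brute_bray_curtis(values):
    """Double-loop oracle straight from the definition."""
    n = len(values)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            denom = values[i].sum() + values[j].sum()
            out[i, j] = (
                np.abs(values[i] - values[j]).sum() / denom if denom else 0.0
            )
    return out


def brute_mantel_p(dx, dy, alternative_r=None):
    """Exhaustive enumeration oracle over all n! joint relabelings of dy."""
    n = len(dx)
    iu = np.triu_indices(n, 1)
    x = dx[iu]
    r_obs = np.corrcoef(x, dy[iu])[0, 1]
    count = total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        r = np.corrcoef(x, dy[np.ix_(p, p)][iu])[0, 1]
        count += r >= r_obs
        total += 1
    return r_obs, count / total


# ------------------------------------------------------------ distances


def test_bray_curtis_matches_definition_oracle():
    rng = np.random.default_rng(0)
    mat = pd.DataFrame(rng.random((5, 4)) * 10)
    dm = pp.abundance_distance(mat)
    np.testing.assert_allclose(dm.data, brute_bray_curtis(mat.to_numpy()))


def test_identical_rows_distance_zero():
    mat = pd.DataFrame([[1, 2, 3]] * 3, index=list("abc"))
    assert pp.abundance_distance(mat).data.max() == 0.0


def test_disjoint_support_distance_one():
    mat = pd.DataFrame([[1, 0], [0, 1], [1, 1]])
    assert pp.abundance_distance(mat)[0, 1] == pytest.approx(1.0)


def test_zero_sample_conventions():
    mat = pd.DataFrame([[0, 0], [0, 0], [1, 2]])
    dm = pp.abundance_distance(mat)
    assert dm[0, 1] == 0.0  # two empty samples agree
    assert dm[0, 2] == 1.0  # empty vs occupied is maximal


def test_env_distance_one_dimensional_unstandardized():
    env = pd.DataFrame({"depth_m": [0.0, 3.0, 6.0]}, index=list("abc"))
    dm = pp.env_distance(env, ["depth_m"], standardize=False)
    assert dm["a", "b"] == pytest.approx(3.0)
    assert dm["a", "c"] == pytest.approx(6.0)
    assert dm["b", "c"] == pytest.approx(3.0)


def test_standardization_equalizes_scales():
    rng = np.random.default_rng(1)
    env = pd.DataFrame(
        {"big": rng.random(6) * 1e4, "small": rng.random(6) * 1e-3}
    )
    sub = env.copy()
    z = (sub - sub.mean()) / sub.std(ddof=1)
    assert z.var(ddof=1).round(9).tolist() == [1.0, 1.0]
    dm = pp.env_distance(env, ["big", "small"], standardize=True)
    oracle = squareform(pdist(z.to_numpy()))
    np.testing.assert_allclose(dm.data, oracle)


def test_zero_variance_variable_excluded_with_warning():
    env = pd.DataFrame({"flat": [1.0] * 4, "ok": [1.0, 2.0, 3.0, 4.0]})
    with pytest.warns(UserWarning, match="flat"):
        dm = pp.env_distance(env, ["flat", "ok"])
    assert dm.data.max() > 0


# ------------------------------------------------------------ Mantel


def _random_pair(seed, n=6):
    rng = np.random.default_rng(seed)
    dx = squareform(pdist(rng.random((n, 3))))
    dy = squareform(pdist(rng.random((n, 3))))
    return dx, dy


def test_identical_matrices_give_r_one_and_minimal_p():
    dx, _ = _random_pair(2)
    res = pp.mantel(dx, dx, n_permutations=999, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p_value >= 1.0 / 1000.0
    assert res.p_value < 0.05


def test_exhaustive_p_equals_enumeration_oracle():
    dx, dy = _random_pair(3, n=5)
    res = pp.mantel(dx, dy, n_permutations="exhaustive")
    r_oracle, p_oracle = brute_mantel_p(dx, dy)
    assert res.r == pytest.approx(r_oracle)
    assert res.p_value == pytest.approx(p_oracle)
    assert res.n_permutations == 120


def test_r_statistic_matches_skbio():
    """Cross-check of the observed statistic against an independent
    implementation (permutation p compared loosely: both are Monte Carlo)."""
    dx, dy = _random_pair(4, n=8)
    ours = pp.mantel(dx, dy, n_permutations=999, seed=1)
    r_sk, p_sk, _ = skbio_mantel(
        DistanceMatrix(dx), DistanceMatrix(dy), method="pearson",
        permutations=999, alternative="greater",
    )
    assert ours.r == pytest.approx(float(r_sk), abs=1e-12)
    assert ours.p_value == pytest.approx(float(p_sk), abs=0.05)


def test_r_invariant_under_common_relabeling():
    dx, dy = _random_pair(5, n=7)
    perm = np.random.default_rng(0).permutation(7)
    r1 = pp.mantel(dx, dy, 99, seed=0).r
    r2 = pp.mantel(dx[np.ix_(perm, perm)], dy[np.ix_(perm, perm)], 99, seed=0).r
    assert r1 == pytest.approx(r2)


def test_label_mismatch_rejected():
    dx, dy = _random_pair(6)
    a = DistanceMatrix(dx, ids=list("abcdef"))
    b = DistanceMatrix(dy, ids=list("abcdeg"))
    with pytest.raises(ValueError, match="mismatch"):
        pp.mantel(a, b)


def test_zero_variance_triangle_rejected():
    flat = np.ones((5, 5)) - np.eye(5)
    dx, _ = _random_pair(7, n=5)
    with pytest.raises(ValueError, match="variance"):
        pp.mantel(dx, flat)


def test_p_respects_permutation_floor():
    dx, _ = _random_pair(8, n=6)
    res = pp.mantel(dx, dx, n_permutations=99, seed=3)
    assert res.p_value >= 1.0 / 100.0


# ------------------------------------------------------------ partial


def test_partial_exhaustive_matches_oracle():
    rng = np.random.default_rng(9)
    pts = rng.random((5, 3))
    dx = squareform(pdist(pts))
    dy = squareform(pdist(pts + 0.3 * rng.random((5, 3))))
    dz = squareform(pdist(rng.random((5, 3))))
    res = pp.partial_mantel(dx, dy, dz, n_permutations="exhaustive")

    iu = np.triu_indices(5, 1)
    x, y, z = dx[iu], dy[iu], dz[iu]

    def partial_r(xv, yv, zv):
        rxy = np.corrcoef(xv, yv)[0, 1]
        rxz = np.corrcoef(xv, zv)[0, 1]
        ryz = np.corrcoef(yv, zv)[0, 1]
        return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))

    r_obs = partial_r(x, y, z)
    count = total = 0
    for perm in itertools.permutations(range(5)):
        p = np.array(perm)
        count += partial_r(x, dy[np.ix_(p, p)][iu], z) >= r_obs
        total += 1
    assert res.r == pytest.approx(r_obs)
    assert res.p_value == pytest.approx(count / total)


def test_controlling_for_near_copy_kills_correlation():
    """dz ~ dy: once dy's structure is partialled out, the strong plain
    correlation collapses toward zero."""
    rng = np.random.default_rng(10)
    pts = rng.random((8, 3))
    dx = squareform(pdist(pts))
    dy = squareform(pdist(pts + 0.2 * rng.random((8, 3))))
    dz = dy * (1 + 1e-6 * rng.random((8, 8)))
    dz = (dz + dz.T) / 2
    np.fill_diagonal(dz, 0)
    plain = pp.mantel(dx, dy, 99, seed=0).r
    res = pp.partial_mantel(dx, dy, dz, 99, seed=0)
    assert plain > 0.5
    assert abs(res.r) < plain / 3


def test_exactly_collinear_control_rejected():
    dx, dy = _random_pair(11, n=6)
    with pytest.raises(ValueError, match="collinear"):
        pp.partial_mantel(dx, dy, dy)


def test_partial_converges_to_plain_with_independent_control():
    """With dz independent of both, partialling changes r only marginally."""
    diffs = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        base = rng.random((7, 3))
        dx = squareform(pdist(base))
        dy = squareform(pdist(base + 0.5 * rng.random((7, 3))))
        dz = squareform(pdist(rng.random((7, 3))))
        plain = pp.mantel(dx, dy, 9, seed=0).r
        partial = pp.partial_mantel(dx, dy, dz, 9, seed=0).r
        diffs.append(abs(plain - partial))
    assert np.mean(diffs) < 0.05


# ------------------------------------------------------------ OLS fits


def test_perfect_line_fits_exactly():
    x = np.arange(10.0)
    r, r2, slope, intercept = pp.expression_abundance_correlation(x, 2 * x + 1)
    assert (r, r2) == (pytest.approx(1.0), pytest.approx(1.0))
    assert slope == pytest.approx(2.0)
    assert intercept == pytest.approx(1.0)


def test_null_r_squared_matches_theory():
    """For independent Gaussians, E[R^2] = 1/(n-1)."""
    rng = np.random.default_rng(12)
    n = 40
    r2s = [
        pp.expression_abundance_correlation(
            rng.standard_normal(n), rng.standard_normal(n)
        )[1]
        for _ in range(400)
    ]
    assert np.mean(r2s) == pytest.approx(1.0 / (n - 1), abs=0.01)


def test_planted_correlation_recovered():
    """y = 0.9 x + noise at matched variance recovers R^2 ~= 0.81."""
    rng = np.random.default_rng(13)
    r2s = []
    for _ in range(200):
        x = rng.standard_normal(50)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(50)
        r2s.append(pp.expression_abundance_correlation(x, y)[1])
    assert np.mean(r2s) == pytest.approx(0.81, abs=0.03)


def test_constant_input_rejected():
    with pytest.raises(ValueError):
        pp.expression_abundance_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
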