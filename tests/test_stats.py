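"""Distance statistics, perMANOVA, NMDS, t-tests, ANOVA, richness regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from scipy.spatial.distance import braycurtis as scipy_bc
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from forageselect.stats import (
    bray_curtis,
    bray_curtis_matrix,
    diet_vs_vegetation_nutrients,
    nmds,
    one_way_anova,
    permanova,
    permanova_pseudo_f,
    pooled_t_test,
    richness_regression,
)

# ------------------------------------------------------------- Bray-Curtis

nonneg_vec = hst.lists(hst.floats(min_value=0, max_value=100), min_size=2, max_size=6)


@pytest.mark.parametrize(
    "u, v, expected",
    [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 0, 0], [0, 2, 3], 1.0),  # disjoint supports
        ([2, 1, 0], [0, 1, 2], 4 / 6),
    ],
)
def test_bray_curtis_values(u, v, expected):
    assert bray_curtis(u, v) == pytest.approx(expected)


def test_bray_curtis_errors():
    with pytest.raises(ValueError):
        bray_curtis([0, 0], [0, 0])
    with pytest.raises(ValueError):
        bray_curtis([-1, 2], [1, 2])


@given(nonneg_vec, nonneg_vec)
def test_bray_curtis_alternative_form(u, v):
    u, v = np.array(u), np.array(v[: len(u)].copy() + [1.0] * (len(u) - len(v)))
    if (u + v).sum() == 0:
        return
    bc = bray_curtis(u, v)
    alt = 1 - 2 * np.minimum(u, v).sum() / (u + v).sum()
    assert bc == pytest.approx(alt, abs=1e-12)
    assert 0 <= bc <= 1


def test_bray_curtis_matrix_matches_scipy(rng):
    x = rng.uniform(0, 5, size=(6, 4))
    dm = bray_curtis_matrix(pd.DataFrame(x))
    for i in range(6):
        for j in range(6):
            expected = 0.0 if i == j else scipy_bc(x[i], x[j])
            assert dm.iloc[i, j] == pytest.approx(expected)


# --------------------------------------------------------------- perMANOVA

def _euclid_dm(x):
    return squareform(pdist(np.atleast_2d(x.T).T))


def test_pseudo_f_equals_anova_f_on_univariate_data(rng):
    for _ in range(20):
        sizes = rng.integers(3, 7, size=3)
        groups = np.repeat(np.arange(3), sizes)
        x = rng.normal(size=groups.size)
        f, r2 = permanova_pseudo_f(_euclid_dm(x[:, None]), groups)
        expected = f_oneway(*(x[groups == g] for g in range(3))).statistic
        assert f == pytest.approx(expected, rel=1e-10)
        assert 0 <= r2 <= 1


def test_permanova_matches_skbio(rng):
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova

    x = rng.uniform(0, 1, size=(12, 4))
    groups = ["a"] * 6 + ["b"] * 6
    dm = bray_curtis_matrix(pd.DataFrame(x))
    res = permanova(dm, groups, n_perm=999, seed=1)
    sk = sk_permanova(DistanceMatrix(dm.to_numpy()), groups, permutations=999)
    assert res.pseudo_f == pytest.approx(float(sk["test statistic"]), rel=1e-9)
    assert abs(res.p_value - float(sk["p-value"])) < 0.08  # same null, different streams


def test_permanova_exact_matches_bruteforce_enumeration(rng):
    x = rng.normal(size=(6, 2))
    groups = np.array([0, 0, 0, 1, 1, 1])
    dm = squareform(pdist(x))
    res = permanova(dm, groups, method="exact")

    # independent brute force: direct SS decomposition over all label orders
    d2 = dm**2
    n = 6

    def brute_f(codes):
        ss_t = d2.sum() / (2 * n)
        ss_w = sum(
            d2[np.ix_(codes == g, codes == g)].sum() / (2 * (codes == g).sum())
            for g in (0, 1)
        )
        return ((ss_t - ss_w) / 1) / (ss_w / (n - 2))

    f_obs = brute_f(groups)
    perms = set(itertools.permutations(groups))
    ge = sum(brute_f(np.array(p)) >= f_obs - 1e-12 for p in perms)
    assert res.pseudo_f == pytest.approx(f_obs, rel=1e-12)
    assert res.p_value == pytest.approx(ge / len(perms))
    # random permutations converge to the exact p
    res_mc = permanova(dm, groups, n_perm=4999, seed=3)
    assert abs(res_mc.p_value - res.p_value) < 0.05


def test_permanova_perfect_separation():
    x = np.array([[1.0, 0, 0]] * 4 + [[0, 0, 1.0]] * 4)
    dm = bray_curtis_matrix(pd.DataFrame(x))
    res = permanova(dm, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
    assert res.r2 == pytest.approx(1.0)
    assert res.p_value <= 0.05


def test_permanova_input_validation():
    dm = np.zeros((4, 4))
    with pytest.raises(ValueError):
        permanova(dm, ["a", "a", "a", "a"])  # single group
    with pytest.raises(ValueError):
        permanova(np.ones((3, 3)), ["a", "b", "a"])  # nonzero diagonal


# -------------------------------------------------------------------- NMDS

def test_nmds_equilateral_triangle_embeds_exactly():
    dm = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    with pytest.warns(UserWarning, match="degenerate"):
        res = nmds(dm, k=2, n_starts=8, seed=0)
    assert res.stress == pytest.approx(0.0, abs=1e-4)


def test_nmds_recovers_planar_configuration(rng):
    pts = rng.uniform(0, 1, size=(10, 2))
    dm = squareform(pdist(pts))
    res = nmds(pd.DataFrame(dm), k=2, n_starts=10, seed=2)
    assert res.stress < 0.01
    assert list(res.coordinates.columns) == ["NMDS1", "NMDS2"]


def test_nmds_deterministic_under_seed(rng):
    pts = rng.uniform(0, 1, size=(8, 3))
    dm = squareform(pdist(pts))
    r1 = nmds(dm, seed=5)
    r2 = nmds(dm, seed=5)
    assert r1.stress == r2.stress
    np.testing.assert_allclose(r1.coordinates, r2.coordinates)


def test_nmds_stress_nonincreasing_in_dimensions(rng):
    pts = rng.uniform(0, 1, size=(9, 4))
    dm = squareform(pdist(pts))
    stresses = [nmds(dm, k=k, n_starts=8, seed=1).stress for k in (1, 2, 3)]
    assert stresses[0] >= stresses[1] - 1e-6
    assert stresses[1] >= stresses[2] - 1e-6


# -------------------------------------------------------------- univariate

def test_pooled_t_reports_pooled_df():
    rng = np.random.default_rng(0)
    res = pooled_t_test(rng.normal(size=9), rng.normal(size=9))
    assert res.df == 16  # two groups of nine -> n1 + n2 - 2


def test_pooled_t_hand_computed_example():
    res = pooled_t_test([0, 0, 1, 1], [1, 1, 2, 2])
    assert res.t == pytest.approx(-2.449, abs=1e-3)
    assert res.df == 6


def test_pooled_t_identical_groups():
    res = pooled_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_pooled_t_degenerate_variance():
    with pytest.raises(ValueError, match="variance"):
        pooled_t_test([1.0, 1.0], [2.0, 2.0])


def test_anova_identical_groups_and_dfs():
    res = one_way_anova([1.0, 2, 3], [1.0, 2, 3], [1.0, 2, 3])
    assert res.f == pytest.approx(0.0)
    assert (res.df_between, res.df_within) == (2, 6)


def test_anova_detects_separated_means(rng):
    groups = [rng.normal(m, 1, size=1000) for m in (0, 0, 3)]
    res = one_way_anova(*groups)
    assert res.p_value < 1e-10


def test_anova_zero_within_variance():
    res = one_way_anova([1.0, 1.0], [2.0, 2.0])
    assert np.isinf(res.f)
    assert res.p_value == 0.0


# -------------------------------------------------------------- regression

def _covariates(rng, n=40):
    return pd.DataFrame(
        rng.normal(size=(n, 4)), columns=["height", "biomass", "diversity", "cp"]
    )


def test_regression_exact_linear_signal(rng):
    X = _covariates(rng)
    y = 3.0 * X["biomass"] + rng.normal(0, 0.01, len(X))
    res = richness_regression(y, X)
    assert res.p_values["biomass"] < 1e-10
    assert res.adj_r2 > 0.99
    # standardized coefficient = raw slope times predictor sd
    assert res.coefficients["biomass"] == pytest.approx(3.0 * X["biomass"].std(ddof=1), rel=0.01)
    lo, hi = res.conf_int.loc["biomass"]
    assert lo < res.coefficients["biomass"] < hi


def test_regression_rank_deficiency_names_columns(rng):
    X = _covariates(rng)
    X["dup"] = X["biomass"]
    with pytest.raises(ValueError, match="collinear"):
        richness_regression(rng.normal(size=len(X)), X)


def test_regression_null_type_one_error(rng):
    alpha, reps = 0.05, 400
    rejections = 0
    for _ in range(reps):
        X = _covariates(rng, n=30)
        y = rng.normal(size=30)
        res = richness_regression(y, X)
        rejections += int(res.p_values["height"] < alpha)
    rate = rejections / reps
    ci = 3 * np.sqrt(alpha * (1 - alpha) / reps)
    assert abs(rate - alpha) < ci


def test_diet_vs_vegetation_nutrient_contrast():
    diet = pd.DataFrame({"diet_cp": [15.0, 16, 15.5], "diet_ndf": [50.0, 51, 50.5],
                         "diet_adf": [30.0, 31, 30.5]})
    veg = pd.DataFrame({"community_cp": [12.0, 12.5, 12.2], "community_ndf": [55.0, 56, 55.5],
                        "community_adf": [30.0, 31, 30.5]})
    out = diet_vs_vegetation_nutrients(diet, veg).set_index("nutrient")
    assert out.loc["cp", "direction"] == 1
    assert out.loc["ndf", "direction"] == -1
    assert out.loc["cp", "p_value"] < 0.05
    assert out.loc["adf", "t"] == pytest.approx(0.0)
    assert out.loc["adf", "p_value"] == pytest.approx(1.0)
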