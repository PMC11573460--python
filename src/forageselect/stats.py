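"""Comparative statistics for the grazing-trial analysis.

Bray-Curtis dissimilarity, permutational MANOVA (distance-based pseudo-F
with a permutation null, Anderson's decomposition) and the bootstrap
machinery are implemented here; NMDS ordination, pooled t-tests, one-way
ANOVA and the dietary-richness regression lean on sklearn / scipy /
statsmodels behind this module's surface.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "bray_curtis",
    "bray_curtis_matrix",
    "permanova",
    "permanova_pseudo_f",
    "PermanovaResult",
    "nmds",
    "NmdsResult",
    "pooled_t_test",
    "one_way_anova",
    "richness_regression",
    "RegressionResult",
    "diet_vs_vegetation_nutrients",
]


# ---------------------------------------------------------------- distances

def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v) of two non-negative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("compositions must have the same length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("compositions must be non-negative")
    denom = (u + v).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero compositions")
    return float(np.abs(u - v).sum() / denom)


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis distance matrix of a samples x features table."""
    x = table.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("compositions must be non-negative")
    n = x.shape[0]
    dm = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        summ = (x[i] + x[i + 1:]).sum(axis=1)
        if np.any(summ == 0):
            raise ValueError("Bray-Curtis undefined for a pair of all-zero rows")
        dm[i, i + 1:] = dm[i + 1:, i] = diff / summ
    return pd.DataFrame(dm, index=table.index, columns=table.index)


# ---------------------------------------------------------------- perMANOVA

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_perm: int
    df_between: int
    df_within: int
    method: str = "permutation"


def _as_square(dm) -> np.ndarray:
    d = dm.to_numpy(dtype=float) if isinstance(dm, pd.DataFrame) else np.asarray(dm, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10) or not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return d


def _ss_decomposition(d2: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    """Total and within-group sums of squared distances (group-size weighted)."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(k):
        idx = codes == g
        ng = int(idx.sum())
        if ng == 0:
            raise ValueError("permanova requires every group to have at least one sample")
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * ng)
    return ss_total, ss_within


def permanova_pseudo_f(dm, groups) -> tuple[float, float]:
    """Observed pseudo-F and R² of a one-way design on a distance matrix."""
    d = _as_square(dm)
    codes, k = _encode_groups(groups, d.shape[0])
    return _pseudo_f_from_d2(d ** 2, codes, k)


def _encode_groups(groups, n: int) -> tuple[np.ndarray, int]:
    labels = np.asarray(groups)
    if labels.shape[0] != n:
        raise ValueError("group labels must match the distance matrix size")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("permanova requires at least 2 groups")
    return codes, len(uniq)


def _pseudo_f_from_d2(d2: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total, ss_within = _ss_decomposition(d2, codes, k)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf, 1.0
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return float(f), float(ss_between / ss_total)


def permanova(
    dm,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "permutation",
) -> PermanovaResult:
    """One-way permutational MANOVA on a distance matrix.

    The pseudo-F statistic is computed from the distance-based sum-of-squares
    decomposition (SS_total over all pairs, SS_within over within-group
    pairs, each divided by group size); the p-value comes from free
    permutation of the group labels with the add-one estimator
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm). ``method="exact"``
    enumerates every distinct label arrangement instead (feasible for small
    n) and reports p = #{F >= F_obs} / #arrangements.
    """
    d = _as_square(dm)
    n = d.shape[0]
    codes, k = _encode_groups(groups, n)
    d2 = d ** 2
    f_obs, r2 = _pseudo_f_from_d2(d2, codes, k)

    if method == "exact":
        seen = set()
        count = 0
        ge = 0
        for perm in itertools.permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            count += 1
            f_p, _ = _pseudo_f_from_d2(d2, np.array(perm), k)
            if f_p >= f_obs - 1e-12:
                ge += 1
        return PermanovaResult(f_obs, r2, ge / count, count, k - 1, n - k, "exact")

    rng = np.random.default_rng(seed)
    ge = 0
    perm = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        f_p, _ = _pseudo_f_from_d2(d2, perm, k)
        if f_p >= f_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_perm)
    return PermanovaResult(f_obs, r2, p, n_perm, k - 1, n - k, "permutation")


# ---------------------------------------------------------------- ordination

@dataclass(frozen=True)
class NmdsResult:
    coordinates: pd.DataFrame = field(repr=False)
    stress: float
    k: int
    n_starts: int


def nmds(dm, k: int = 2, n_starts: int = 20, seed: int = 0, max_iter: int = 500) -> NmdsResult:
    """Nonmetric multidimensional scaling with Kruskal stress-1.

    Best of ``n_starts`` random-start monotone-regression fits; the
    returned configuration is rotated to its principal axes.
    """
    from sklearn.manifold import MDS

    d = _as_square(dm)
    n = d.shape[0]
    if n < k + 1:
        raise ValueError(f"nmds in {k} dimensions needs at least {k + 1} samples")
    off = d[~np.eye(n, dtype=bool)]
    if np.allclose(off, off[0]):
        warnings.warn("all pairwise distances are equal; the ordination is degenerate")
    common = dict(
        n_components=k, n_init=n_starts, random_state=seed, max_iter=max_iter,
        eps=1e-9, normalized_stress=True,
    )
    try:
        model = MDS(metric_mds=False, metric="precomputed", init="random", **common)
    except TypeError:  # sklearn < 1.9 API
        model = MDS(metric=False, dissimilarity="precomputed", **common)
    coords = model.fit_transform(d)
    coords = coords - coords.mean(axis=0)
    # principal-axis rotation so the configuration is orientation-stable
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    index = dm.index if isinstance(dm, pd.DataFrame) else pd.RangeIndex(n)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return NmdsResult(pd.DataFrame(coords, index=index, columns=cols), float(model.stress_), k, n_starts)


# ---------------------------------------------------------------- univariate

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float


def pooled_t_test(x, y) -> TTestResult:
    """Equal-variance two-sample t-test; df = n_x + n_y - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TTestResult(0.0, len(x) + len(y) - 2, 1.0)
        raise ValueError("zero pooled variance with unequal means")
    res = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(res.statistic), len(x) + len(y) - 2, float(res.pvalue))


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p_value: float


def one_way_anova(*groups) -> AnovaResult:
    """Classical one-way ANOVA over two or more groups."""
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.f_oneway(*arrays)
    f = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(f):  # zero within-group variance
        means = [a.mean() for a in arrays]
        if np.ptp(means) == 0:
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
    return AnovaResult(f, k - 1, n - k, p)


# ---------------------------------------------------------------- regression

@dataclass(frozen=True)
class RegressionResult:
    coefficients: pd.Series = field(repr=False)
    wald_stats: pd.Series = field(repr=False)
    p_values: pd.Series = field(repr=False)
    conf_int: pd.DataFrame = field(repr=False)
    adj_r2: float
    n: int
    standardized: bool


def richness_regression(
    richness,
    covariates: pd.DataFrame,
    standardize: bool = True,
) -> RegressionResult:
    """OLS of dietary richness on vegetation covariates with Wald tests.

    Predictors are z-standardized by default so coefficients are comparable
    effect sizes across units; per-coefficient Wald statistic = estimate/SE
    with its two-sided p, 95% confidence intervals, and adjusted R².
    """
    import statsmodels.api as sm

    y = np.asarray(richness, dtype=float)
    X = covariates.astype(float).copy()
    if len(y) != len(X):
        raise ValueError("response and covariates must have the same length")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more observations than predictors + 1")
    sds = X.std(ddof=1)
    zero_sd = list(sds.index[sds == 0])
    if zero_sd:
        raise ValueError(f"constant predictor columns: {zero_sd}")
    if standardize:
        X = (X - X.mean()) / sds
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pairs = [
            (a, b)
            for a in corr.index
            for b in corr.columns
            if a < b and corr.loc[a, b] > 1 - 1e-8
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {pairs or list(X.columns)}")
    design = sm.add_constant(X)
    fit = sm.OLS(y, design).fit()
    keep = X.columns
    return RegressionResult(
        coefficients=fit.params[keep],
        wald_stats=fit.tvalues[keep],
        p_values=fit.pvalues[keep],
        conf_int=fit.conf_int().loc[keep].set_axis(["ci_low", "ci_high"], axis=1),
        adj_r2=float(fit.rsquared_adj),
        n=len(y),
        standardized=standardize,
    )


def diet_vs_vegetation_nutrients(
    diet: pd.DataFrame,
    vegetation: pd.DataFrame,
    nutrients: tuple = ("cp", "ndf", "adf"),
) -> pd.DataFrame:
    """Pooled t-tests of diet vs vegetation nutrient content, per nutrient.

    ``diet`` has columns diet_cp/diet_ndf/diet_adf; ``vegetation`` has
    community_cp/community_ndf/community_adf. Direction is +1 when the diet
    mean exceeds the vegetation mean.
    """
    rows = []
    for nut in nutrients:
        x = diet[f"diet_{nut}"].to_numpy(dtype=float)
        y = vegetation[f"community_{nut}"].to_numpy(dtype=float)
        res = pooled_t_test(x, y)
        rows.append(
            {
                "nutrient": nut,
                "t": res.t,
                "df": res.df,
                "p_value": res.p_value,
                "direction": int(np.sign(x.mean() - y.mean())),
            }
        )
    return pd.DataFrame(rows)
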