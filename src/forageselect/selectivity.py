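"""Jacobs' electivity index and tests for departure from neutral selection.

A food item's use ``r`` (its proportion in the diet) is compared with its
availability ``p`` (its proportion of above-ground biomass):

    D = (r - p) / (r + p - 2 r p)

D ranges from -1 (complete avoidance) through 0 (use proportional to
availability) to +1 (exclusive preference). D is undefined when an item is
absent from both diet and vegetation (r = p = 0) or constitutes both
entirely (r = p = 1); such cells are returned as NaN and excluded from
tests rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "jacobs_d",
    "selectivity_table",
    "selectivity_test",
    "item_tests",
    "SelectivityTest",
]

#: above this sample size the signed-rank null is approximated as normal
_EXACT_N_MAX = 25


def jacobs_d(r, p):
    """Jacobs' selectivity index D for use ``r`` and availability ``p``.

    Vectorized; returns NaN where the index is undefined (r = p = 0 or
    r = p = 1, i.e. zero denominator).
    """
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((r < 0) | (r > 1)) or np.any((p < 0) | (p > 1)):
        raise ValueError("r and p must be proportions in [0, 1]")
    denom = r + p - 2.0 * r * p
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom == 0.0, np.nan, (r - p) / np.where(denom == 0, 1.0, denom))
    return d.item() if d.ndim == 0 else d


def selectivity_table(dra: pd.DataFrame, vra: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Per-sample, per-item selectivity in long format.

    Parameters
    ----------
    dra : DataFrame
        Samples x food items, rows on the simplex (diet proportions).
    vra : DataFrame or Series
        Availability per food item. A Series applies the same availability
        to every sample; a DataFrame must be indexed like ``dra`` (sample ->
        its plot/period availability).
    """
    if isinstance(vra, pd.Series):
        vra = pd.DataFrame(
            np.tile(vra.reindex(dra.columns).to_numpy(), (len(dra), 1)),
            index=dra.index,
            columns=dra.columns,
        )
    vra = vra.reindex(index=dra.index, columns=dra.columns)
    if vra.isna().any().any():
        raise ValueError("availability table does not cover every sample/item in the diet table")
    rows = []
    for item in dra.columns:
        r = dra[item].to_numpy()
        p = vra[item].to_numpy()
        d = jacobs_d(r, p)
        rows.append(
            pd.DataFrame(
                {"sample": dra.index, "item": item, "r": r, "p": p, "d": np.atleast_1d(d)}
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class SelectivityTest:
    item: str | None
    n: int
    statistic: float
    p_value: float
    direction: int  # sign of the median D; 0 when no information
    method: str


def selectivity_test(
    d_values,
    zero_method: str = "wilcox",
    alternative: str = "two-sided",
    item: str | None = None,
) -> SelectivityTest:
    """Wilcoxon signed-rank test of Jacobs' D against zero.

    NaN (undefined) values are dropped. Exact null distribution up to
    n = 25 after zero handling, normal approximation with continuity
    correction above. ``zero_method`` is "wilcox" (drop zeros before
    ranking, the common package default) or "pratt".
    """
    d = np.asarray(d_values, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no defined selectivity values to test")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        # every animal used the item exactly in proportion to availability
        return SelectivityTest(item, 0, np.nan, np.nan, 0, "no-information")
    n_eff = nonzero.size if zero_method == "wilcox" else d.size
    method = "exact" if n_eff <= _EXACT_N_MAX else "approx"
    res = sps.wilcoxon(
        d,
        zero_method=zero_method,
        correction=(method == "approx"),
        alternative=alternative,
        method=method,
    )
    return SelectivityTest(
        item=item,
        n=int(d.size),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=int(np.sign(np.median(d))),
        method=method,
    )


def item_tests(long_table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Run :func:`selectivity_test` per food item of a long selectivity table."""
    out = []
    for item, grp in long_table.groupby("item", sort=False):
        try:
            res = selectivity_test(grp["d"].to_numpy(), item=item, **kwargs)
        except ValueError:
            continue
        out.append(res.__dict__)
    return pd.DataFrame(out)
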