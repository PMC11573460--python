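"""Vegetation-survey summaries: biomass, diversity, availability, nutrients.

Quadrat clippings (species-level dry biomass per quadrat) are pooled per
plot and period into total biomass, Shannon-Wiener diversity H', species
richness, the relative abundance of vegetation components (VRA, the
availability side of selectivity) grouped into six food items, and
biomass-weighted community nutrient content (CP/NDF/ADF).

Abundance measure: the survey clips and weighs biomass, so relative
abundance uses biomass as n_i by default; count-based input works through
the same functions (any non-negative abundance column).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FOOD_ITEMS",
    "relative_abundance",
    "shannon_index",
    "food_item_availability",
    "community_nutrients",
    "food_item_nutrients",
    "summarize",
]

#: the six food items: five dominant plant families plus pooled forbs
FOOD_ITEMS = ("Poaceae", "Cyperaceae", "Rosaceae", "Amaryllidaceae", "Fabaceae", "forbs")

QUADRAT_COLUMNS = ("plot", "period", "quadrat", "species_id", "biomass")


def _check_quadrats(records: pd.DataFrame) -> None:
    missing = set(("species_id", "biomass")) - set(records.columns)
    if missing:
        raise ValueError(f"quadrat table missing columns: {sorted(missing)}")
    if len(records) == 0:
        raise ValueError("no records: quadrat table is empty")
    if (records["biomass"] < 0).any():
        bad = records.index[records["biomass"] < 0][0]
        raise ValueError(f"negative biomass at row {bad}")


def relative_abundance(records: pd.DataFrame) -> pd.Series:
    """Per-species relative abundance p_i = n_i / N for one plot/period.

    Biomass is the abundance measure n_i; rows for the same species are
    pooled (the 10 quadrats of a plot are combined before analysis).
    """
    _check_quadrats(records)
    totals = records.groupby("species_id", sort=False)["biomass"].sum()
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("empty community: total biomass is zero")
    return totals / grand


def shannon_index(p) -> float:
    """Shannon-Wiener diversity H' = -sum p_i ln p_i of a relative-abundance vector.

    Zero entries contribute nothing (0 ln 0 := 0). H' = ln S for a uniform
    community of S species and 0 for a monoculture.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("relative abundances must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError("relative abundances must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def food_item_availability(records: pd.DataFrame, family_map: dict) -> pd.Series:
    """VRA: the share of each food item in total above-ground biomass.

    ``family_map`` maps every species_id to one of :data:`FOOD_ITEMS`
    (species outside the five dominant families map to "forbs"). Returns a
    simplex Series over all six items, zeros included.
    """
    _check_quadrats(records)
    species = records["species_id"].unique()
    unmapped = [s for s in species if s not in family_map]
    if unmapped:
        raise ValueError(f"species without a food-item mapping: {sorted(unmapped)}")
    bad_items = {family_map[s] for s in species} - set(FOOD_ITEMS)
    if bad_items:
        raise ValueError(f"unknown food items in map: {sorted(bad_items)}")
    items = records["species_id"].map(family_map)
    shares = records.groupby(items, sort=False)["biomass"].sum()
    total = shares.sum()
    if total <= 0:
        raise ValueError("empty community: total biomass is zero")
    return (shares / total).reindex(FOOD_ITEMS, fill_value=0.0).rename("vra")


def community_nutrients(records: pd.DataFrame, nutrients: pd.DataFrame) -> pd.Series:
    """Biomass-weighted community CP/NDF/ADF (percent of dry matter).

    ``nutrients`` is indexed by species_id with columns cp, ndf, adf.
    """
    _check_quadrats(records)
    totals = records.groupby("species_id", sort=False)["biomass"].sum()
    totals = totals[totals > 0]
    missing = [s for s in totals.index if s not in nutrients.index]
    if missing:
        raise ValueError(f"nutrient values missing for species: {sorted(missing)}")
    w = totals / totals.sum()
    vals = nutrients.loc[totals.index, ["cp", "ndf", "adf"]]
    if vals.isna().any().any():
        raise ValueError("nutrient table contains missing values for present species")
    out = vals.mul(w, axis=0).sum()
    return out.rename(index={"cp": "community_cp", "ndf": "community_ndf", "adf": "community_adf"})


def food_item_nutrients(
    records: pd.DataFrame, nutrients: pd.DataFrame, family_map: dict
) -> pd.DataFrame:
    """Biomass-weighted CP/NDF/ADF per food item (rows = items present).

    This is the nutrient content attributed to each food item when diet
    proportions are converted to diet nutrients.
    """
    _check_quadrats(records)
    totals = records.groupby("species_id", sort=False)["biomass"].sum()
    totals = totals[totals > 0]
    missing = [s for s in totals.index if s not in nutrients.index]
    if missing:
        raise ValueError(f"nutrient values missing for species: {sorted(missing)}")
    df = pd.DataFrame(
        {
            "item": [family_map[s] for s in totals.index],
            "biomass": totals.to_numpy(),
        },
        index=totals.index,
    ).join(nutrients[["cp", "ndf", "adf"]])
    out = df.groupby("item").apply(
        lambda g: pd.Series(
            {c: np.average(g[c], weights=g["biomass"]) for c in ("cp", "ndf", "adf")}
        ),
        include_groups=False,
    )
    return out.reindex([i for i in FOOD_ITEMS if i in out.index])


def summarize(
    records: pd.DataFrame,
    nutrients: pd.DataFrame,
    family_map: dict,
    quadrat_area_m2: float = 0.25,
    heights: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Plot-level summary per (plot, period): one row per replicate plot.

    Returns total_biomass (g m-2, from the quadrat area), richness, H',
    the six VRA columns, community nutrients and, if a ``height`` column or
    table is available, mean height (cm).
    """
    for col in ("plot", "period"):
        if col not in records.columns:
            raise ValueError(f"quadrat table missing columns: ['{col}']")
    _check_quadrats(records)
    rows = []
    for (plot, period), grp in records.groupby(["plot", "period"], sort=True):
        n_quadrats = grp["quadrat"].nunique() if "quadrat" in grp.columns else 1
        total = grp["biomass"].sum() / (n_quadrats * quadrat_area_m2)
        p = relative_abundance(grp)
        row = {
            "plot": plot,
            "period": period,
            "total_biomass": total,
            "richness": int((p > 0).sum()),
            "shannon": shannon_index(p.to_numpy()),
        }
        vra = food_item_availability(grp, family_map)
        row.update({f"vra_{item}": vra[item] for item in FOOD_ITEMS})
        row.update(community_nutrients(grp, nutrients).to_dict())
        if "height" in grp.columns:
            present = grp[grp["biomass"] > 0]
            row["mean_height"] = float(
                np.average(present["height"], weights=present["biomass"])
            )
        elif heights is not None:
            present = grp[grp["biomass"] > 0]
            h = heights.reindex(present["species_id"])["height"].to_numpy()
            row["mean_height"] = float(np.average(h, weights=present["biomass"]))
        rows.append(row)
    out = pd.DataFrame(rows)
    if "strategy" in records.columns:
        strat = records.groupby(["plot", "period"])["strategy"].first()
        out.insert(0, "strategy", [strat[(r["plot"], r["period"])] for _, r in out.iterrows()])
    return out
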