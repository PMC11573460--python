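"""Diet composition from fecal DNA-metabarcoding read tables.

The pipeline starts at denoised ASV (amplicon sequence variant) read
counts. ASVs are assigned to plant species by exact, unambiguous sequence
identity against a reference barcode set; assigned reads are summed into
six food items and normalized into the relative read abundance (DRA), the
use side of selectivity. Food-item proportions times the items' nutrient
content give the diet's CP/NDF/ADF; dietary richness is the expected
number of ASVs in a depth-standardized subsample, estimated by bootstrap
rarefaction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "assign_exact",
    "dra",
    "diet_nutrients",
    "bootstrap_richness",
    "diet_composition",
]


def assign_exact(asv_seqs: dict, reference: dict) -> dict:
    """Assign ASVs to species by unique 100%-identity matches.

    Parameters
    ----------
    asv_seqs : dict
        ASV id -> nucleotide sequence.
    reference : dict
        species_id -> reference barcode sequence.

    Returns ASV id -> species_id, or None for ASVs that match no reference
    or whose sequence occurs under more than one species (ambiguous).
    Matching is case-insensitive and gap-free.
    """
    if not reference:
        raise ValueError("empty reference barcode set")
    by_seq: dict[str, str | None] = {}
    for species, seq in reference.items():
        key = str(seq).upper()
        by_seq[key] = None if key in by_seq else species  # duplicate -> ambiguous
    return {asv: by_seq.get(str(seq).upper()) for asv, seq in asv_seqs.items()}


def dra(
    counts: pd.DataFrame,
    taxonomy: dict,
    family_map: dict,
    items: tuple = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Relative read abundance per food item, per sample.

    ``counts`` is samples x ASV ids; ``taxonomy`` maps ASV -> species (None
    = unassigned); ``family_map`` maps species -> food item. Unassigned
    reads are excluded from the denominator; their fraction of each
    sample's depth is reported alongside.

    Returns (dra_table, unassigned_fraction).
    """
    from .vegetation import FOOD_ITEMS

    items = tuple(items) if items is not None else FOOD_ITEMS
    if (counts.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    item_of_asv = {}
    for asv in counts.columns:
        sp = taxonomy.get(asv)
        if sp is None:
            continue
        if sp not in family_map:
            raise ValueError(f"assigned species {sp!r} missing from the food-item map")
        item_of_asv[asv] = family_map[sp]
    depth = counts.sum(axis=1)
    assigned_cols = list(item_of_asv)
    grouped = counts[assigned_cols].T.groupby(pd.Series(item_of_asv)).sum().T
    grouped = grouped.reindex(columns=items, fill_value=0.0)
    assigned_depth = grouped.sum(axis=1)
    zero = assigned_depth[assigned_depth <= 0]
    if len(zero):
        raise ValueError(f"no assigned reads in samples: {list(zero.index)}")
    table = grouped.div(assigned_depth, axis=0)
    unassigned = (1.0 - assigned_depth / depth).rename("unassigned_fraction")
    return table, unassigned


def diet_nutrients(dra_table: pd.DataFrame, item_nutrients: pd.DataFrame) -> pd.DataFrame:
    """Diet CP/NDF/ADF as the DRA-weighted mean of food-item nutrient content.

    ``item_nutrients`` is indexed by food item with columns cp, ndf, adf —
    typically the biomass-weighted item values of the matching plot/period
    vegetation.
    """
    needed = dra_table.columns[(dra_table > 0).any(axis=0)]
    missing = [i for i in needed if i not in item_nutrients.index]
    if missing:
        raise ValueError(f"nutrient values missing for consumed items: {missing}")
    vals = item_nutrients.reindex(dra_table.columns)[["cp", "ndf", "adf"]].fillna(0.0)
    out = dra_table.to_numpy() @ vals.to_numpy()
    return pd.DataFrame(
        out, index=dra_table.index, columns=["diet_cp", "diet_ndf", "diet_adf"]
    )


def bootstrap_richness(
    counts,
    depth: int,
    iterations: int = 1000,
    seed: int = 0,
    replace: bool = False,
) -> float:
    """Expected ASV richness of a depth-standardized subsample.

    Mean, over bootstrap iterations, of the number of distinct ASVs in a
    subsample of ``depth`` reads drawn without replacement (rarefaction;
    ``replace=True`` switches to multinomial resampling).
    """
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    total = int(c.sum())
    if depth < 1 or iterations < 1:
        raise ValueError("depth and iterations must be >= 1")
    if not replace and depth > total:
        raise ValueError(f"depth {depth} exceeds sample total reads {total}")
    rng = np.random.default_rng(seed)
    if not replace and depth == total:
        return float(len(c))
    richness = np.empty(iterations)
    for i in range(iterations):
        if replace:
            sub = rng.multinomial(depth, c / total)
        else:
            sub = rng.multivariate_hypergeometric(c, depth)
        richness[i] = np.count_nonzero(sub)
    return float(richness.mean())


def diet_composition(
    counts: pd.DataFrame,
    taxonomy: dict,
    family_map: dict,
    item_nutrients: pd.DataFrame | None = None,
    depth: int | str = "auto",
    iterations: int = 1000,
    seed: int = 0,
    replace: bool = False,
) -> pd.DataFrame:
    """Per-sample diet summary: DRA, diet nutrients, standardized richness.

    ``depth="auto"`` standardizes richness at the minimum assigned-read
    depth across the samples being compared.
    """
    table, unassigned = dra(counts, taxonomy, family_map)
    assigned = counts[[a for a in counts.columns if taxonomy.get(a) is not None]]
    assigned_depth = assigned.sum(axis=1)
    std_depth = int(assigned_depth.min()) if depth == "auto" else int(depth)
    rich = pd.Series(
        [
            bootstrap_richness(
                assigned.loc[s].to_numpy(),
                std_depth,
                iterations=iterations,
                seed=seed + i,
                replace=replace,
            )
            for i, s in enumerate(assigned.index)
        ],
        index=assigned.index,
        name="richness",
    )
    out = table.add_prefix("dra_")
    if item_nutrients is not None:
        out = out.join(diet_nutrients(table, item_nutrients))
    out["richness"] = rich
    out["unassigned_fraction"] = unassigned
    out["assigned_depth"] = assigned_depth
    return out
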