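"""Ground-truth generator: pools, quadrats, diets, reads, traces, fecal chemistry."""

import numpy as np
import pandas as pd
import pytest

from forageselect.intake import estimate_intake
from forageselect.synthetic import (
    GroundTruth,
    TrialDesign,
    expected_diet,
    generate_accel_trace,
    generate_animal_diets,
    generate_fecal_samples,
    generate_quadrats,
    generate_reads,
    generate_species_pool,
)
from forageselect.vegetation import FOOD_ITEMS


def test_species_pool_default_has_all_families():
    pool = generate_species_pool(seed=0)
    assert len(pool) == 37
    assert set(pool.table["family"]) == set(FOOD_ITEMS)
    assert pool.table["mean_rel_biomass"].sum() == pytest.approx(1.0)
    assert not pool.table["barcode"].duplicated().any()
    # forbs emulate higher CP / lower NDF than grasses
    by_fam = pool.table.groupby("family")[["cp", "ndf"]].mean()
    assert by_fam.loc["forbs", "cp"] > by_fam.loc["Poaceae", "cp"]
    assert by_fam.loc["forbs", "ndf"] < by_fam.loc["Poaceae", "ndf"]


def test_species_pool_single_species():
    pool = generate_species_pool(n_species=1, family_weights={"Poaceae": 1.0}, seed=0)
    assert len(pool) == 1
    assert pool.table["mean_rel_biomass"].iloc[0] == pytest.approx(1.0)


def test_species_pool_deterministic_under_seed():
    p1 = generate_species_pool(seed=42)
    p2 = generate_species_pool(seed=42)
    pd.testing.assert_frame_equal(p1.table, p2.table)


def test_species_pool_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        generate_species_pool(family_weights={"Poaceae": 0.5, "forbs": 0.2})
    with pytest.raises(ValueError, match="n_species"):
        generate_species_pool(n_species=3)


def test_quadrat_layout(small_pool, trial_design):
    q = generate_quadrats(small_pool, trial_design, quadrats_per_plot=10, seed=1)
    # 10 quadrats x 3 plots = 30 quadrats per plot group and period
    one = q[(q["strategy"] == "LA") & (q["period"] == 1)]
    assert one.groupby("plot")["quadrat"].nunique().tolist() == [10, 10, 10]
    per_species = one.groupby(["plot", "species_id"]).size()
    assert (per_species == 10).all()
    # lambs-mixed and ewes-mixed share plots: groups are LA, M, EA
    assert set(q["strategy"]) == {"LA", "M", "EA"}


def test_quadrat_concentration_limit(small_pool):
    design = TrialDesign(strategies=("LA",), plots_per_strategy=1, periods=1)
    q = generate_quadrats(small_pool, design, quadrats_per_plot=5, dispersion=1e7, seed=2)
    shares = q.groupby("quadrat", group_keys=False)["biomass"].apply(lambda s: s / s.sum())
    mean_share = small_pool.table["mean_rel_biomass"].to_numpy()
    for _, grp in q.groupby("quadrat"):
        comp = (grp["biomass"] / grp["biomass"].sum()).to_numpy()
        np.testing.assert_allclose(comp, mean_share, atol=1e-3)


def test_quadrat_family_share_law_of_large_numbers():
    pool = generate_species_pool(
        n_species=8,
        family_weights={"Poaceae": 0.6, "forbs": 0.4},
        seed=5,
    )
    design = TrialDesign(strategies=("LA",), plots_per_strategy=1, periods=1)
    q = generate_quadrats(pool, design, quadrats_per_plot=10_000, dispersion=20, seed=6)
    fam = q["species_id"].map(pool.family_map())
    share = q.groupby(fam)["biomass"].sum() / q["biomass"].sum()
    assert share["Poaceae"] == pytest.approx(0.6, abs=0.01)


def test_expected_diet_preference_weighting():
    avail = pd.Series({"forbs": 0.1, "Poaceae": 0.9}).reindex(FOOD_ITEMS, fill_value=0.0)
    mean = expected_diet(avail, {"forbs": 9.0, "Poaceae": 1.0})
    assert mean["forbs"] == pytest.approx(0.5)
    assert mean["Poaceae"] == pytest.approx(0.5)
    # neutral preference reproduces availability
    neutral = expected_diet(avail, {})
    pd.testing.assert_series_equal(neutral, avail, check_names=False)


def test_animal_diets_concentration_limit(small_pool):
    avail = small_pool.family_shares()
    truth = generate_animal_diets(small_pool, avail, {}, n_animals=5, concentration=1e8, seed=1)
    for _, row in truth.diets_family.iterrows():
        np.testing.assert_allclose(row.to_numpy(), avail.to_numpy(), atol=1e-3)
    # species-level diets consistent with family-level
    fam_from_species = truth.diets_species.T.groupby(
        small_pool.table.set_index("species_id")["family"]
    ).sum().T.reindex(columns=FOOD_ITEMS, fill_value=0.0)
    np.testing.assert_allclose(fam_from_species, truth.diets_family, atol=1e-12)


def test_animal_diets_validation(small_pool):
    avail = small_pool.family_shares()
    with pytest.raises(ValueError, match="preference"):
        generate_animal_diets(small_pool, avail, {"forbs": 0.0}, n_animals=2)
    with pytest.raises(ValueError, match="sum to 1"):
        generate_animal_diets(small_pool, avail * 2, {}, n_animals=2)


def test_sparse_species_spread_preserves_family_totals(small_pool):
    avail = small_pool.family_shares()
    truth = generate_animal_diets(
        small_pool, avail, {}, n_animals=6, seed=2, species_concentration=3.0
    )
    fam_from_species = truth.diets_species.T.groupby(
        small_pool.table.set_index("species_id")["family"]
    ).sum().T.reindex(columns=FOOD_ITEMS, fill_value=0.0)
    np.testing.assert_allclose(fam_from_species, truth.diets_family, atol=1e-9)


def test_reads_single_species_and_row_sums(small_pool):
    diets = pd.DataFrame(
        [[1.0] + [0.0] * (len(small_pool) - 1)], columns=small_pool.species_ids
    )
    counts, asv_seqs = generate_reads(diets, small_pool, depth=1000, seed=0)
    assert counts.to_numpy().sum() == 1000
    assert counts.iloc[0, 0] == 1000
    assert len(asv_seqs) == len(small_pool)
    with pytest.raises(ValueError):
        generate_reads(diets, small_pool, depth=0)


def test_reads_proportions_converge(small_pool):
    avail = small_pool.family_shares()
    truth = generate_animal_diets(small_pool, avail, {}, n_animals=1, concentration=1e8, seed=3)
    depth = 100_000
    counts, _ = generate_reads(truth.diets_species, small_pool, depth=depth, seed=4)
    props = counts.iloc[0].to_numpy() / depth
    p = truth.diets_species.iloc[0].to_numpy()
    se = np.sqrt(p * (1 - p) / depth)
    assert np.all(np.abs(props - p) <= 3 * se + 1e-9)


def test_accel_trace_length_and_determinism():
    trace, labels = generate_accel_trace(duration_h=13.0, sample_rate=1.0, seed=8)
    assert len(trace) == 46_800  # 13 h x 3600 s
    assert len(labels) == len(trace)
    t2, l2 = generate_accel_trace(duration_h=13.0, sample_rate=1.0, seed=8)
    pd.testing.assert_frame_equal(trace, t2)
    assert (labels == l2).all()


def test_accel_trace_validation():
    with pytest.raises(ValueError):
        generate_accel_trace(sample_rate=0)
    with pytest.raises(ValueError):
        generate_accel_trace(mean_bout_s={"grazing": 0.0, "non-grazing": 0.0})


def _truth(n=4):
    idx = [f"a{i}" for i in range(n)]
    return GroundTruth(
        fo=pd.Series(200.0, index=idx),
        omd=pd.Series(0.31, index=idx),
        ash=pd.Series(20.0, index=idx),
    )


def test_fecal_samples_noise_free_marker():
    fecal = generate_fecal_samples(_truth(), noise_cv=0.0, seed=0)
    assert np.allclose(fecal["tio2_conc"], 2.5 / 200.0)
    # inverse consistency through the intake chain
    out = estimate_intake(fecal)
    assert np.allclose(out["fo"], 200.0, rtol=1e-12)
    assert np.allclose(out["omd"], 0.31, rtol=1e-12)
    truth = _truth()
    assert np.allclose(out["omi"], truth.omi, rtol=1e-12)


def test_fecal_samples_rejects_asymptotic_omd():
    t = _truth()
    t.omd = pd.Series(0.899, index=t.fo.index)
    with pytest.raises(ValueError, match="invertible"):
        generate_fecal_samples(t, noise_cv=0.0)


def test_ground_truth_derived_quantities():
    t = _truth(1)
    assert t.fom.iloc[0] == pytest.approx(160.0)
    assert t.omi.iloc[0] == pytest.approx(160.0 / 0.69)
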