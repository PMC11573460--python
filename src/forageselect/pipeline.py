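"""End-to-end pipeline: simulate -> vegetation -> behavior -> intake -> diet
-> selectivity -> stats, driven by one config and one global seed.

Each stage reruns deterministically: the global seed and the stage name
derive a per-stage seed, and every output is a plain TSV/FASTA/JSON file
whose sha256 is recorded in a manifest.
"""

from __future__ import annotations

import copy
import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import diet as dt
from . import io
from . import selectivity as sel
from . import stats as st
from . import synthetic as syn
from . import vegetation as veg
from .intake import estimate_intake
from .vegetation import FOOD_ITEMS

__all__ = ["DEFAULT_CONFIG", "load_config", "stage_seed", "simulate_trial", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "design": {
        "strategies": ["LA", "LM", "EM", "EA"],
        "plots_per_strategy": 3,
        "periods": 3,
        "animals_per_plot": 3,
    },
    "species_pool": {"n_species": 37, "barcode_length": 80},
    "quadrats": {"quadrats_per_plot": 10, "dispersion": 50.0},
    "diets": {
        "concentration": 100.0,
        "species_concentration": 3.0,
        # strategy -> per-item preference weights (unlisted items weigh 1);
        # mixed grazers and lone ewes favor high-CP forbs, lone lambs avoid
        # them and lean on Rosaceae
        "preference": {
            "LA": {"forbs": 0.4, "Rosaceae": 3.0},
            "LM": {"forbs": 3.0},
            "EM": {"forbs": 3.0},
            "EA": {"forbs": 2.0},
        },
    },
    "reads": {"depth": 50000, "depth_cv": 0.3},
    "fecal": {"dose": 2.5, "noise_cv": 0.05, "fo_mean": 400.0, "fo_cv": 0.15,
              "omd_range": [0.29, 0.335], "ash_range": [15.0, 25.0]},
    "accel": {"animals_per_strategy": 1, "duration_h": 13.0, "sample_rate": 1.0},
    "behavior": {"threshold": 0.1, "epoch": 60.0, "smoothing_window": 2.0},
    "diet_analysis": {"depth": "auto", "iterations": 1000},
    "stats": {"n_perm": 999, "n_starts": 20,
              "permanova_pairs": [["LA", "LM"], ["LM", "EM"], ["EA", "EM"]]},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Config from YAML, deep-merged over the built-in defaults."""
    import yaml

    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config at {path} must be a YAML mapping")
    return _deep_merge(DEFAULT_CONFIG, user)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 100003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ------------------------------------------------------------------ simulate

def simulate_trial(config: dict, outdir) -> dict:
    """Generate every raw input layer plus the ground-truth bundle.

    Writes species pool, quadrats, reference/ASV FASTA, read counts, fecal
    chemistry, accelerometer traces and ground-truth TSVs into ``outdir``;
    returns the in-memory objects for downstream stages.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    design = syn.TrialDesign(
        strategies=tuple(config["design"]["strategies"]),
        plots_per_strategy=config["design"]["plots_per_strategy"],
        periods=config["design"]["periods"],
        animals_per_plot=config["design"]["animals_per_plot"],
        seed=seed,
    )
    pool = syn.generate_species_pool(
        seed=stage_seed(seed, "species_pool"), **config["species_pool"]
    )
    quadrats = syn.generate_quadrats(
        pool, design, seed=stage_seed(seed, "quadrats"), **config["quadrats"]
    )
    family_map = pool.family_map()

    # diets per (strategy, plot, period) from the plot's availability
    animals = design.animals()
    pref_cfg = config["diets"]["preference"]
    conc = config["diets"]["concentration"]
    fam_rows, sp_rows, ids = [], [], []
    for (strategy, plot), grp in animals.groupby(["strategy", "plot"], sort=False):
        for period in range(1, design.periods + 1):
            q = quadrats[(quadrats["plot"] == plot) & (quadrats["period"] == period)]
            avail = veg.food_item_availability(q, family_map)
            truth = syn.generate_animal_diets(
                pool,
                avail,
                pref_cfg.get(strategy, {}),
                n_animals=len(grp),
                concentration=conc,
                seed=stage_seed(seed, f"diets/{strategy}/{plot}/{period}"),
                animal_ids=list(grp["animal"]),
                species_concentration=config["diets"].get("species_concentration"),
            )
            fam_rows.append(truth.diets_family)
            sp_rows.append(truth.diets_species)
            ids += [f"{a}|P{period}" for a in grp["animal"]]
    diets_family = pd.concat(fam_rows).set_axis(ids)
    diets_species = pd.concat(sp_rows).set_axis(ids)

    # library sizes vary between samples, as in real sequencing runs
    rcfg = config["reads"]
    depth_rng = np.random.default_rng(stage_seed(seed, "read_depths"))
    if rcfg.get("depth_cv", 0.3) > 0:
        sig = np.sqrt(np.log1p(rcfg.get("depth_cv", 0.3) ** 2))
        depths = np.maximum(
            100, (rcfg["depth"] * depth_rng.lognormal(-0.5 * sig**2, sig, len(ids))).astype(int)
        )
    else:
        depths = rcfg["depth"]
    counts, asv_seqs = syn.generate_reads(
        diets_species, pool, depth=depths, seed=stage_seed(seed, "reads")
    )

    fcfg = config["fecal"]
    rng = np.random.default_rng(stage_seed(seed, "fecal_truth"))
    n = len(ids)
    sigma = np.sqrt(np.log1p(fcfg["fo_cv"] ** 2))
    truth = syn.GroundTruth(
        diets_family=diets_family,
        diets_species=diets_species,
        fo=pd.Series(
            fcfg["fo_mean"] * rng.lognormal(-0.5 * sigma**2, sigma, n), index=ids, name="fo"
        ),
        omd=pd.Series(rng.uniform(*fcfg["omd_range"], n), index=ids, name="omd"),
        ash=pd.Series(rng.uniform(*fcfg["ash_range"], n), index=ids, name="ash"),
    )
    fecal = syn.generate_fecal_samples(
        truth, dose=fcfg["dose"], noise_cv=fcfg["noise_cv"], seed=stage_seed(seed, "fecal")
    ).rename(columns={"index": "sample"})

    acfg = config["accel"]
    traces, bout_labels = {}, {}
    for strategy in design.strategies:
        chosen = animals[animals["strategy"] == strategy]["animal"].iloc[
            : acfg["animals_per_strategy"]
        ]
        for animal in chosen:
            trace, labels = syn.generate_accel_trace(
                duration_h=acfg["duration_h"],
                sample_rate=acfg["sample_rate"],
                seed=stage_seed(seed, f"accel/{animal}"),
            )
            traces[animal] = trace
            bout_labels[animal] = labels
    truth.bout_labels = bout_labels

    # ------------------------------------------------------------- write out
    io.write_table(pool.table, outdir / "species_pool.tsv")
    io.write_table(quadrats, outdir / "quadrats.tsv")
    io.write_fasta(pool.barcodes(), outdir / "reference_barcodes.fasta")
    io.write_fasta(asv_seqs, outdir / "asv_sequences.fasta")
    io.write_table(
        counts.reset_index().rename(columns={"index": "sample"}), outdir / "read_counts.tsv"
    )
    io.write_table(fecal, outdir / "fecal_chemistry.tsv")
    io.write_table(animals, outdir / "animals.tsv")
    for animal, trace in traces.items():
        io.write_table(trace, outdir / f"accel_{animal}.tsv")
    io.write_table(
        diets_family.reset_index().rename(columns={"index": "sample"}),
        outdir / "truth_diets_family.tsv",
    )
    io.write_table(
        pd.DataFrame(
            {"sample": ids, "fo": truth.fo, "omd": truth.omd, "ash": truth.ash,
             "fom": truth.fom, "omi": truth.omi}
        ),
        outdir / "truth_intake.tsv",
    )
    return {
        "design": design,
        "pool": pool,
        "quadrats": quadrats,
        "family_map": family_map,
        "animals": animals,
        "counts": counts,
        "asv_seqs": asv_seqs,
        "fecal": fecal,
        "traces": traces,
        "truth": truth,
    }


# --------------------------------------------------------------- run_pipeline

def _sample_keys(sample_ids, animals: pd.DataFrame) -> pd.DataFrame:
    """Split 'animal|P<period>' sample ids into animal / strategy / plot / period."""
    meta = animals.set_index("animal")
    rows = []
    for s in sample_ids:
        animal, per = s.rsplit("|P", 1)
        rows.append(
            {
                "sample": s,
                "animal": animal,
                "strategy": meta.loc[animal, "strategy"],
                "plot": meta.loc[animal, "plot"],
                "period": int(per),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage on a simulated trial and write a provenance manifest."""
    outdir = Path(outdir)
    manifest: dict = {"seed": int(config["seed"]), "stages": {}}

    def record(stage: str, paths: list[Path], params: dict) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in paths},
            "params": params,
        }

    sim = simulate_trial(config, outdir / "simulated")
    record(
        "simulate",
        sorted((outdir / "simulated").glob("*")),
        {"seed": config["seed"], **{k: config[k] for k in ("design", "species_pool", "quadrats", "reads", "fecal", "accel")}},
    )

    # vegetation summaries per plot/period
    nutrients = sim["pool"].nutrient_table()
    veg_summary = veg.summarize(sim["quadrats"], nutrients, sim["family_map"])
    p = io.write_table(veg_summary, outdir / "vegetation_summary.tsv")
    record("vegetation", [p], {})

    # behavior: epoch ODBA -> labels -> daily grazing time
    bcfg = config["behavior"]
    rows = []
    for animal, trace in sim["traces"].items():
        series = bh.classify(
            bh.epoch_odba(trace, smoothing_window=bcfg["smoothing_window"], epoch=bcfg["epoch"]),
            threshold=bcfg["threshold"],
        )
        rows.append({"animal": animal, "grazing_h": bh.daily_grazing_time(series)})
    behavior_out = pd.DataFrame(rows)
    p = io.write_table(behavior_out, outdir / "daily_grazing_time.tsv")
    record("behavior", [p], bcfg)

    # intake chain
    intake_out = estimate_intake(sim["fecal"], dose=config["fecal"]["dose"])
    p = io.write_table(intake_out, outdir / "intake.tsv")
    record("intake", [p], {"dose": config["fecal"]["dose"]})

    # diet composition
    dcfg = config["diet_analysis"]
    taxonomy = dt.assign_exact(sim["asv_seqs"], sim["pool"].barcodes())
    keys = _sample_keys(sim["counts"].index, sim["animals"])
    comp_rows = []
    for (plot, period), grp in keys.groupby(["plot", "period"], sort=True):
        q = sim["quadrats"][(sim["quadrats"]["plot"] == plot) & (sim["quadrats"]["period"] == period)]
        item_nut = veg.food_item_nutrients(q, nutrients, sim["family_map"])
        comp = dt.diet_composition(
            sim["counts"].loc[grp.index],
            taxonomy,
            sim["family_map"],
            item_nutrients=item_nut,
            depth=dcfg["depth"],
            iterations=dcfg["iterations"],
            seed=stage_seed(config["seed"], f"richness/{plot}/{period}"),
        )
        comp_rows.append(comp)
    composition = pd.concat(comp_rows).loc[sim["counts"].index]
    p = io.write_table(
        composition.reset_index().rename(columns={"index": "sample"}),
        outdir / "diet_composition.tsv",
    )
    record("diet", [p], dcfg)

    # selectivity: DRA vs the matching plot/period VRA
    dra_table = composition[[f"dra_{i}" for i in FOOD_ITEMS]].set_axis(list(FOOD_ITEMS), axis=1)
    vs = veg_summary.set_index(["plot", "period"])
    vra_rows = pd.DataFrame(
        [
            vs.loc[(keys.loc[s, "plot"], keys.loc[s, "period"]),
                   [f"vra_{i}" for i in FOOD_ITEMS]].to_numpy()
            for s in dra_table.index
        ],
        index=dra_table.index,
        columns=list(FOOD_ITEMS),
    )
    long = sel.selectivity_table(dra_table, vra_rows)
    tests = sel.item_tests(long)
    p1 = io.write_table(long, outdir / "selectivity.tsv")
    p2 = io.write_table(tests, outdir / "selectivity_tests.tsv")
    record("selectivity", [p1, p2], {})

    # comparative statistics
    scfg = config["stats"]
    stats_out: dict = {}
    perm_rows, nmds_paths = [], []
    for pair in scfg["permanova_pairs"]:
        mask = keys["strategy"].isin(pair)
        sub = dra_table.loc[mask.to_numpy()]
        labels = keys.loc[sub.index, "strategy"].to_numpy()
        dm = st.bray_curtis_matrix(sub)
        res = st.permanova(
            dm, labels, n_perm=scfg["n_perm"], seed=stage_seed(config["seed"], f"permanova/{pair}")
        )
        ord_res = st.nmds(
            dm, n_starts=scfg["n_starts"], seed=stage_seed(config["seed"], f"nmds/{pair}")
        )
        tag = "_vs_".join(pair)
        nmds_paths.append(
            io.write_table(
                ord_res.coordinates.reset_index().rename(columns={"index": "sample"}),
                outdir / f"nmds_{tag}.tsv",
            )
        )
        perm_rows.append(
            {"pair": tag, "pseudo_f": res.pseudo_f, "r2": res.r2, "p_value": res.p_value,
             "n_perm": res.n_perm, "stress": ord_res.stress}
        )
    stats_out["permanova"] = perm_rows

    # intake and grazing-time contrasts (LA vs LM, EA vs EM) where present
    strategies = set(keys["strategy"])
    contrasts = []
    merged = intake_out.merge(keys.reset_index(), on="sample")
    for a, b in (("LA", "LM"), ("EA", "EM")):
        if {a, b} <= strategies:
            res = st.pooled_t_test(
                merged.loc[merged["strategy"] == a, "omi"],
                merged.loc[merged["strategy"] == b, "omi"],
            )
            contrasts.append({"contrast": f"{a}_vs_{b}", "variable": "omi",
                              "t": res.t, "df": res.df, "p_value": res.p_value})
    stats_out["t_tests"] = contrasts

    # diet vs vegetation nutrients per strategy
    veg_by_sample = pd.DataFrame(
        [
            vs.loc[(keys.loc[s, "plot"], keys.loc[s, "period"]),
                   ["community_cp", "community_ndf", "community_adf"]].to_numpy()
            for s in composition.index
        ],
        index=composition.index,
        columns=["community_cp", "community_ndf", "community_adf"],
    )
    nut_rows = []
    for strategy, grp in keys.groupby("strategy", sort=False):
        res = st.diet_vs_vegetation_nutrients(
            composition.loc[grp.index], veg_by_sample.loc[grp.index]
        )
        res.insert(0, "strategy", strategy)
        nut_rows.append(res)
    nutrient_tests = pd.concat(nut_rows, ignore_index=True)
    p3 = io.write_table(nutrient_tests, outdir / "nutrient_tests.tsv")

    # dietary-richness regression per strategy
    covars = pd.DataFrame(
        [
            vs.loc[(keys.loc[s, "plot"], keys.loc[s, "period"]),
                   ["mean_height", "total_biomass", "shannon",
                    "community_cp", "community_ndf", "community_adf"]].to_numpy()
            for s in composition.index
        ],
        index=composition.index,
        columns=["height", "biomass", "diversity", "cp", "ndf", "adf"],
    )
    reg_rows = []
    for strategy, grp in keys.groupby("strategy", sort=False):
        try:
            res = st.richness_regression(
                composition.loc[grp.index, "richness"], covars.loc[grp.index]
            )
        except ValueError:
            continue
        for name in res.coefficients.index:
            reg_rows.append(
                {"strategy": strategy, "predictor": name,
                 "coefficient": res.coefficients[name], "wald": res.wald_stats[name],
                 "p_value": res.p_values[name],
                 "ci_low": res.conf_int.loc[name, "ci_low"],
                 "ci_high": res.conf_int.loc[name, "ci_high"],
                 "adj_r2": res.adj_r2}
            )
    regression = pd.DataFrame(reg_rows)
    p4 = io.write_table(regression, outdir / "richness_regression.tsv")

    summary_path = outdir / "stats_summary.json"
    summary_path.write_text(json.dumps(stats_out, indent=2, default=float) + "\n")
    record("stats", [*nmds_paths, p3, p4, summary_path], scfg)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return {
        "manifest": manifest,
        "vegetation": veg_summary,
        "behavior": behavior_out,
        "intake": intake_out,
        "composition": composition,
        "selectivity": long,
        "selectivity_tests": tests,
        "stats": stats_out,
        "nutrient_tests": nutrient_tests,
        "regression": regression,
        "sim": sim,
    }
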