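"""Synthetic grazing-trial generator with known ground truth.

Emulates the four data layers of a sheep grazing-strategy trial — quadrat
vegetation surveys, tri-axial accelerometry, marker-dosed fecal chemistry,
and fecal DNA-metabarcoding read tables — under three plot groups (lambs
alone LA; lambs + ewes mixed LM/EM, co-located; ewes alone EA), three
replicate plots and three sampling periods. Every layer is generated from
explicit ground-truth parameters (true diets, fecal output, digestibility,
behavior bouts) so downstream estimators can be checked for recovery.

Generative choices: quadrat compositions are Dirichlet draws around the
species pool's mean relative biomass scaled by a lognormal quadrat total;
animal diets are Dirichlet draws around availability x preference
(renormalized), spread over species within a family by within-family
availability; reads are multinomial over species barcodes; behavior is a
two-state Markov bout process with per-state dynamic-acceleration scale
set so expected ODBA matches the requested per-behavior mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intake import DEFAULT_OMD_MODEL, OmdModel
from .vegetation import FOOD_ITEMS

__all__ = [
    "SpeciesPool",
    "TrialDesign",
    "GroundTruth",
    "generate_species_pool",
    "generate_quadrats",
    "generate_animal_diets",
    "generate_reads",
    "generate_accel_trace",
    "generate_fecal_samples",
    "DEFAULT_FAMILY_WEIGHTS",
    "DEFAULT_NUTRIENT_RANGES",
]

#: mean biomass share per food item; the five named families together hold
#: 85% of above-ground biomass (the trial site reports > 81%)
DEFAULT_FAMILY_WEIGHTS = {
    "Poaceae": 0.45,
    "Cyperaceae": 0.15,
    "Rosaceae": 0.12,
    "Amaryllidaceae": 0.06,
    "Fabaceae": 0.07,
    "forbs": 0.15,
}

#: per-family (low, high) nutrient ranges, percent of dry matter; forbs and
#: legumes carry more crude protein and less fiber than graminoids
DEFAULT_NUTRIENT_RANGES = {
    "Poaceae": {"cp": (8, 12), "ndf": (55, 68), "adf": (30, 38)},
    "Cyperaceae": {"cp": (9, 13), "ndf": (55, 65), "adf": (28, 36)},
    "Rosaceae": {"cp": (10, 14), "ndf": (45, 55), "adf": (28, 35)},
    "Amaryllidaceae": {"cp": (11, 15), "ndf": (40, 50), "adf": (25, 32)},
    "Fabaceae": {"cp": (16, 22), "ndf": (35, 45), "adf": (25, 32)},
    "forbs": {"cp": (14, 20), "ndf": (35, 48), "adf": (22, 30)},
}

#: per-family (low, high) mean plant height, cm
DEFAULT_HEIGHT_RANGES = {
    "Poaceae": (15, 45),
    "Cyperaceae": (10, 30),
    "Rosaceae": (5, 20),
    "Amaryllidaceae": (15, 35),
    "Fabaceae": (10, 30),
    "forbs": (5, 25),
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SpeciesPool:
    """Species-level ground truth: family, nutrients, barcode, mean biomass share."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"species_id", "family", "cp", "ndf", "adf", "barcode", "mean_rel_biomass"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"species pool missing columns: {sorted(missing)}")
        t = self.table
        for col in ("cp", "ndf", "adf"):
            if ((t[col] < 0) | (t[col] > 100)).any():
                raise ValueError(f"{col} must lie in [0, 100]")
        if t["barcode"].duplicated().any():
            raise ValueError("barcodes must be unique across species")
        if not np.isclose(t["mean_rel_biomass"].sum(), 1.0, atol=1e-9):
            raise ValueError("mean_rel_biomass must sum to 1 over the pool")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def species_ids(self) -> list:
        return list(self.table["species_id"])

    def family_map(self) -> dict:
        return dict(zip(self.table["species_id"], self.table["family"]))

    def barcodes(self) -> dict:
        return dict(zip(self.table["species_id"], self.table["barcode"]))

    def nutrient_table(self) -> pd.DataFrame:
        return self.table.set_index("species_id")[["cp", "ndf", "adf"]]

    def family_shares(self) -> pd.Series:
        shares = self.table.groupby("family")["mean_rel_biomass"].sum()
        return shares.reindex(FOOD_ITEMS, fill_value=0.0)


@dataclass(frozen=True)
class TrialDesign:
    """Layout of the grazing trial.

    LM and EM animals are co-located in shared mixed plots; plot ids are
    "LA1..", "M1.." (shared by LM and EM) and "EA1..".
    """

    strategies: tuple = ("LA", "LM", "EM", "EA")
    plots_per_strategy: int = 3
    periods: int = 3
    animals_per_plot: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.plots_per_strategy, self.periods, self.animals_per_plot) < 1:
            raise ValueError("design counts must be >= 1")
        unknown = set(self.strategies) - {"LA", "LM", "EM", "EA"}
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")

    @staticmethod
    def plot_group(strategy: str) -> str:
        return "M" if strategy in ("LM", "EM") else strategy

    def plot_groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.strategies:
            g = self.plot_group(s)
            if g not in seen:
                seen.append(g)
        return seen

    def plots(self) -> dict[str, list[str]]:
        return {g: [f"{g}{i + 1}" for i in range(self.plots_per_strategy)] for g in self.plot_groups()}

    def animals(self) -> pd.DataFrame:
        rows = []
        for strategy in self.strategies:
            group = self.plot_group(strategy)
            for p in range(self.plots_per_strategy):
                for a in range(self.animals_per_plot):
                    rows.append(
                        {
                            "animal": f"{strategy}-p{p + 1}-a{a + 1}",
                            "strategy": strategy,
                            "plot": f"{group}{p + 1}",
                        }
                    )
        return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Per-animal-period truth used by recovery tests; plumbing, not data."""

    diets_family: pd.DataFrame | None = None   # (animal, period) x food item
    diets_species: pd.DataFrame | None = None  # (animal, period) x species
    fo: pd.Series | None = None                # g fecal DM day-1
    omd: pd.Series | None = None               # fraction
    ash: pd.Series | None = None               # percent of fecal DM
    bout_labels: dict | None = None            # animal -> per-sample labels

    @property
    def fom(self) -> pd.Series:
        return self.fo * (1.0 - self.ash / 100.0)

    @property
    def omi(self) -> pd.Series:
        return self.fom / (1.0 - self.omd)


def _check_simplex(w: np.ndarray, name: str) -> None:
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError(f"{name} must be non-negative and sum to 1")


def _unique_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        seq = "".join(rng.choice(_BASES, size=length))
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def generate_species_pool(
    n_species: int = 37,
    family_weights: dict | None = None,
    nutrient_ranges: dict | None = None,
    barcode_length: int = 80,
    seed: int = 0,
) -> SpeciesPool:
    """Draw a species pool with family labels, nutrients and unique barcodes.

    Every requested family gets at least one species; within a family, the
    family's biomass share is split over its species by a flat Dirichlet.
    """
    weights = dict(DEFAULT_FAMILY_WEIGHTS if family_weights is None else family_weights)
    ranges = DEFAULT_NUTRIENT_RANGES if nutrient_ranges is None else nutrient_ranges
    families = list(weights)
    w = np.array([weights[f] for f in families], dtype=float)
    _check_simplex(w, "family_weights")
    if n_species < len(families):
        raise ValueError("n_species must be at least the number of families")
    rng = np.random.default_rng(seed)
    # one species per family guaranteed, remainder proportional to weight
    fam_assign = list(families)
    extra = rng.choice(len(families), size=n_species - len(families), p=w)
    fam_assign += [families[i] for i in extra]
    rng.shuffle(fam_assign)

    barcodes = _unique_barcodes(n_species, barcode_length, rng)
    rows = []
    for i, fam in enumerate(fam_assign):
        r = ranges[fam]
        rows.append(
            {
                "species_id": f"sp{i + 1:03d}",
                "family": fam,
                "cp": rng.uniform(*r["cp"]),
                "ndf": rng.uniform(*r["ndf"]),
                "adf": rng.uniform(*r["adf"]),
                "height_cm": rng.uniform(*DEFAULT_HEIGHT_RANGES.get(fam, (5, 40))),
                "barcode": barcodes[i],
            }
        )
    table = pd.DataFrame(rows)
    rel = np.zeros(n_species)
    for fam in families:
        idx = np.flatnonzero(table["family"] == fam)
        split = rng.dirichlet(np.ones(len(idx)))
        rel[idx] = weights[fam] * split
    table["mean_rel_biomass"] = rel / rel.sum()
    return SpeciesPool(table)


def generate_quadrats(
    pool: SpeciesPool,
    design: TrialDesign,
    quadrats_per_plot: int = 10,
    dispersion: float = 50.0,
    mean_quadrat_biomass: float = 40.0,
    biomass_sigma: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Quadrat clipping records for every plot group, plot, period.

    Per-quadrat species composition ~ Dirichlet(dispersion * mean shares);
    per-quadrat total dry biomass (g per quadrat) ~ lognormal around
    ``mean_quadrat_biomass``. Each plot/period carries exactly
    ``quadrats_per_plot`` records per species (zeros possible only in the
    Dirichlet tail, biomass stays positive).
    """
    if quadrats_per_plot < 1:
        raise ValueError("quadrats_per_plot must be >= 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    alpha = dispersion * pool.table["mean_rel_biomass"].to_numpy()
    species = pool.species_ids
    heights = (
        pool.table.set_index("species_id")["height_cm"]
        if "height_cm" in pool.table.columns
        else None
    )
    mu = np.log(mean_quadrat_biomass) - 0.5 * biomass_sigma**2
    rows = []
    for group, plots in design.plots().items():
        for plot in plots:
            for period in range(1, design.periods + 1):
                for q in range(1, quadrats_per_plot + 1):
                    comp = rng.dirichlet(alpha)
                    total = rng.lognormal(mu, biomass_sigma)
                    for sp, share in zip(species, comp):
                        rec = {
                            "strategy": group,
                            "plot": plot,
                            "period": period,
                            "quadrat": f"q{q}",
                            "species_id": sp,
                            "biomass": total * share,
                        }
                        if heights is not None:
                            rec["height"] = heights[sp]
                        rows.append(rec)
    return pd.DataFrame(rows)


def expected_diet(availability: pd.Series, preference: dict | pd.Series) -> pd.Series:
    """Expected family diet: availability x preference, renormalized."""
    avail = availability.reindex(FOOD_ITEMS, fill_value=0.0).astype(float)
    _check_simplex(avail.to_numpy(), "availability")
    pref = pd.Series(preference, dtype=float).reindex(FOOD_ITEMS, fill_value=1.0)
    if (pref <= 0).any():
        raise ValueError("preference weights must be > 0")
    w = avail * pref
    return w / w.sum()


def generate_animal_diets(
    pool: SpeciesPool,
    availability: pd.Series,
    preference: dict | pd.Series,
    n_animals: int,
    concentration: float = 100.0,
    seed: int = 0,
    animal_ids: list | None = None,
    species_concentration: float | None = None,
) -> GroundTruth:
    """True family- and species-level diet proportions for ``n_animals``.

    Family diets are Dirichlet draws about availability x preference
    (renormalized); within a family, the family share is spread over its
    species proportionally to within-family availability (mean relative
    biomass). Items with zero availability are dropped before drawing.

    ``species_concentration`` switches the within-family spread from the
    deterministic availability split to a per-animal Dirichlet draw around
    it (low values give sparse, individual diets in which many species are
    effectively absent); family-level proportions are unaffected.
    """
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    mean = expected_diet(availability, preference)
    present = mean[mean > 0]
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(concentration * present.to_numpy(), size=n_animals)
    fam_df = pd.DataFrame(0.0, index=range(n_animals), columns=FOOD_ITEMS)
    fam_df.loc[:, present.index] = draws
    if animal_ids is not None:
        fam_df.index = pd.Index(animal_ids, name="animal")

    # within-family species split by availability share
    t = pool.table
    within = (
        t["mean_rel_biomass"] / t.groupby("family")["mean_rel_biomass"].transform("sum")
    ).to_numpy()
    fam_arr = t["family"].to_numpy()
    if species_concentration is None:
        spread = np.zeros((len(t), len(FOOD_ITEMS)))
        for j, fam in enumerate(FOOD_ITEMS):
            idx = np.flatnonzero(fam_arr == fam)
            spread[idx, j] = within[idx]
        sp = fam_df.to_numpy() @ spread.T
    else:
        if species_concentration <= 0:
            raise ValueError("species_concentration must be > 0")
        sp = np.zeros((n_animals, len(t)))
        for j, fam in enumerate(FOOD_ITEMS):
            idx = np.flatnonzero(fam_arr == fam)
            if len(idx) == 0:
                continue
            alpha = np.maximum(species_concentration * within[idx], 1e-3)
            draws_w = rng.dirichlet(alpha, size=n_animals)
            sp[:, idx] = fam_df.to_numpy()[:, [j]] * draws_w
    sp_df = pd.DataFrame(sp, index=fam_df.index, columns=t["species_id"])
    return GroundTruth(diets_family=fam_df, diets_species=sp_df)


def generate_reads(
    diets_species: pd.DataFrame,
    pool: SpeciesPool,
    depth: int = 50_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Multinomial read counts over species barcodes (one ASV per barcode).

    ``depth`` is either one library size for every sample (row sums then
    equal ``depth`` exactly) or a per-sample array of library sizes.
    Returns (counts samples x ASV ids, asv_id -> sequence).
    """
    depths = np.broadcast_to(np.asarray(depth, dtype=np.int64), (len(diets_species),))
    if np.any(depths < 1):
        raise ValueError("sequencing depth must be >= 1")
    rng = np.random.default_rng(seed)
    probs = diets_species[pool.species_ids].to_numpy(dtype=float)
    probs = probs / probs.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(d, p) for d, p in zip(depths, probs)])
    asv_ids = [f"ASV{i + 1:04d}" for i in range(len(pool))]
    asv_seqs = dict(zip(asv_ids, pool.table["barcode"]))
    return pd.DataFrame(counts, index=diets_species.index, columns=asv_ids), asv_seqs


def generate_accel_trace(
    mean_bout_s: dict | None = None,
    odba_params: dict | None = None,
    duration_h: float = 13.0,
    sample_rate: float = 1.0,
    grazing_start: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Bout-structured tri-axial trace and its true per-sample labels.

    A two-state Markov chain (grazing / non-grazing) with geometric bout
    lengths of the given means; within a bout the per-axis dynamic
    acceleration is zero-mean Gaussian with scale chosen so the expected
    per-sample ODBA equals the state's (bout-perturbed) mean; the static
    component is gravity projected through a slowly drifting orientation.
    Setting a state's mean_bout to 0 removes that state entirely.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    mean_bout_s = dict(mean_bout_s or {"grazing": 1800.0, "non-grazing": 1200.0})
    if all(v <= 0 for v in mean_bout_s.values()):
        raise ValueError("at least one behavior needs a positive mean bout length")
    odba_params = dict(odba_params or {"grazing": (0.3, 0.05), "non-grazing": (0.02, 0.005)})
    n = int(round(duration_h * 3600 * sample_rate))
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate

    states = ("grazing", "non-grazing")
    labels = np.empty(n, dtype=object)
    # |ODBA| of 3 iid N(0, s): E = 3 s sqrt(2/pi)
    scale_factor = 3.0 * np.sqrt(2.0 / np.pi)
    dyn = np.zeros((n, 3))
    state = "grazing" if grazing_start and mean_bout_s["grazing"] > 0 else "non-grazing"
    i = 0
    while i < n:
        mean_len = mean_bout_s[state]
        if mean_len <= 0:
            state = states[1 - states.index(state)]
            continue
        bout_len = max(1, int(rng.geometric(min(1.0, dt / mean_len))))
        j = min(n, i + bout_len)
        mean, sd = odba_params[state]
        bout_mean = max(1e-4, rng.normal(mean, sd))
        s = bout_mean / scale_factor
        dyn[i:j] = rng.normal(0.0, s, size=(j - i, 3))
        labels[i:j] = state
        i = j
        other = states[1 - states.index(state)]
        if mean_bout_s[other] > 0:
            state = other
    # gravity through a slowly drifting pitch/roll random walk
    pitch = np.cumsum(rng.normal(0, 0.002, n))
    roll = np.cumsum(rng.normal(0, 0.002, n))
    static = np.column_stack(
        [np.sin(pitch), -np.sin(roll) * np.cos(pitch), np.cos(roll) * np.cos(pitch)]
    )
    trace = pd.DataFrame(
        {
            "timestamp": np.arange(n) * dt,
            "ax": static[:, 0] + dyn[:, 0],
            "ay": static[:, 1] + dyn[:, 1],
            "az": static[:, 2] + dyn[:, 2],
        }
    )
    return trace, labels


def generate_fecal_samples(
    truth: GroundTruth,
    dose: float = 2.5,
    noise_cv: float = 0.05,
    seed: int = 0,
    model: OmdModel = DEFAULT_OMD_MODEL,
) -> pd.DataFrame:
    """Marker-consistent fecal chemistry from ground-truth FO/OMD/ash.

    TiO2 concentration is dose / true FO with multiplicative lognormal
    noise of coefficient of variation ``noise_cv`` (unit mean); fecal CP
    inverts the digestibility regression at the true OMD (rejected outside
    its invertible band); ash is carried through so derived FOM matches
    the true FOM.
    """
    if dose <= 0:
        raise ValueError("marker dose must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    for name in ("fo", "omd", "ash"):
        if getattr(truth, name) is None:
            raise ValueError(f"ground truth lacks {name}")
    rng = np.random.default_rng(seed)
    fo = truth.fo.to_numpy(dtype=float)
    conc = dose / fo
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        conc = conc * rng.lognormal(-0.5 * sigma**2, sigma, size=len(conc))
    fcp = model.invert(truth.omd.to_numpy(dtype=float))
    out = pd.DataFrame(
        {
            "tio2_conc": conc,
            "fcp": np.atleast_1d(fcp),
            "ash": truth.ash.to_numpy(dtype=float),
        },
        index=truth.fo.index,
    )
    return out.reset_index()
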