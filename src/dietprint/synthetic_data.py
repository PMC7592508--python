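"""Seeded synthetic survey populations and parameter tables.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without any external download:

* a stratified multistage design with >= 2 PSUs per stratum and skewed
  (log-normal) sampling weights, like a national examination survey;
* energy intake generated first, food grams and index-component amounts
  second conditional on energy, so density-based scoring is well defined
  for every record;
* a latent "healthfulness" factor per individual whose influence is set by
  a gradient parameter: it raises adequacy-component densities, lowers
  moderation-component amounts, and tilts food-gram shares toward
  commodities with positive healthfulness loadings (fruit, vegetables,
  nuts), inducing the diet-quality/intake correlation the analysis probes;
* commodity loss fractions, recipe tables (with a configurable unmapped
  share mirroring a stale crosswalk), scoring standards, and a small
  crop/livestock parameter set with at least one commodity flagged
  non-domestic to exercise closed-system reapportionment.

Identical seeds yield identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .diet_quality import ahei2010_standards, hei2015_standards
from .errors import DesignError
from .foodprint import AgronomicParameters

FOOD_GROUPS = [
    "fruits",
    "vegetables",
    "grains",
    "dairy",
    "meat_poultry_fish",
    "nuts_seeds_legumes",
    "sweets_beverages",
    "oils",
]

# latent-healthfulness loading per food group: positive groups are eaten
# more by individuals with healthier diets
GROUP_LOADINGS = {
    "fruits": 1.0,
    "vegetables": 0.9,
    "grains": 0.2,
    "dairy": 0.3,
    "meat_poultry_fish": -0.3,
    "nuts_seeds_legumes": 0.8,
    "sweets_beverages": -1.0,
    "oils": 0.0,
}

_PLANT_GROUP_TO_CATEGORY = {
    "fruits": "fruits",
    "vegetables": "vegetables",
    "grains": "grains",
    "nuts_seeds_legumes": "nuts",
    "sweets_beverages": "sweeteners",
    "oils": "feed_grains_oilseeds",
}

_ANIMAL_PRODUCTS = ["milk", "beef", "pork", "chicken"]

#: tolerance on energy/intake consistency: total food grams lie within
#: [energy/2.5, energy/0.8] (overall energy density 0.8-2.5 kcal/g)
ENERGY_DENSITY_RANGE = (0.8, 2.5)


@dataclass(frozen=True)
class SurveyDesignSpec:
    """Stratified two-stage design: strata x PSUs x individuals."""

    n_strata: int = 15
    psus_per_stratum: int = 2
    individuals_per_psu: int = 40
    weight_log_mean: float = float(np.log(260_000.0))
    weight_log_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strata <= 0 or self.individuals_per_psu <= 0:
            raise DesignError("counts must be positive")
        if self.psus_per_stratum < 2:
            raise DesignError("variance estimation requires >= 2 PSUs per stratum")

    @property
    def n_individuals(self) -> int:
        return self.n_strata * self.psus_per_stratum * self.individuals_per_psu


@dataclass(frozen=True)
class PopulationSpec:
    """Dietary heterogeneity of the simulated population."""

    n_foods: int = 30
    n_commodities: int = 18
    energy_mean: float = 2100.0
    energy_sd: float = 650.0
    energy_floor: float = 400.0
    gradient: float = 0.6  # strength of the healthfulness/intake correlation
    age_min: float = 2.0
    age_max: float = 80.0
    sex_male_fraction: float = 0.49
    unmapped_food_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_foods <= 0 or self.n_commodities <= 0:
            raise DesignError("counts must be positive")
        if self.energy_floor <= 0:
            raise DesignError("energy floor must be positive")
        if not np.isfinite(self.gradient):
            raise DesignError("gradient must be finite")


def _commodity_frame(n_commodities: int) -> pd.DataFrame:
    rows = []
    for i in range(n_commodities):
        grp = FOOD_GROUPS[i % len(FOOD_GROUPS)]
        rows.append(
            {
                "commodity_id": f"C{i:03d}",
                "food_group": grp,
                "loading": GROUP_LOADINGS[grp],
            }
        )
    return pd.DataFrame(rows)


def generate_parameter_tables(
    n_foods: int = 30,
    n_commodities: int = 18,
    n_crops: int = 12,
    seed: int = 0,
    *,
    unmapped_food_fraction: float = 0.1,
) -> dict:
    """Generate every parameter table the pipeline consumes.

    Returns a dict with keys ``recipes``, ``loss_profiles``,
    ``commodity_groups``, ``standards_hei2015``, ``standards_ahei2010``,
    and ``agronomic`` (an :class:`AgronomicParameters`).
    """
    if min(n_foods, n_commodities, n_crops) <= 0:
        raise DesignError("counts must be positive")
    rng = np.random.default_rng(seed)
    commodities = _commodity_frame(n_commodities)

    # --- recipe table: each mapped food splits over 1-3 commodities -------
    n_unmapped = int(round(unmapped_food_fraction * n_foods))
    mapped_foods = [f"F{i:03d}" for i in range(n_foods - n_unmapped)]
    recipe_rows = []
    for f in mapped_foods:
        k = int(rng.integers(1, 4))
        chosen = rng.choice(commodities["commodity_id"], size=k, replace=False)
        fracs = rng.dirichlet(np.ones(k))
        fracs = fracs / fracs.sum()  # exact normalization
        for c, fr in zip(chosen, fracs):
            recipe_rows.append({"food_id": f, "commodity_id": c, "fraction": float(fr)})
    recipes = pd.DataFrame(recipe_rows)

    # --- loss profiles: LAFA-like magnitudes ------------------------------
    inedible_hi = commodities["food_group"].isin(
        ["fruits", "vegetables", "meat_poultry_fish"]
    )
    loss_profiles = pd.DataFrame(
        {
            "commodity_id": commodities["commodity_id"],
            "retail_loss_fraction": rng.uniform(0.03, 0.12, n_commodities),
            "inedible_fraction": np.where(
                inedible_hi,
                rng.uniform(0.05, 0.35, n_commodities),
                rng.uniform(0.0, 0.10, n_commodities),
            ),
            "consumer_waste_fraction": rng.uniform(0.15, 0.45, n_commodities),
        }
    )

    agronomic = _generate_agronomic(commodities, n_crops, rng)

    return {
        "recipes": recipes,
        "loss_profiles": loss_profiles,
        "commodity_groups": commodities.set_index("commodity_id")["food_group"],
        "standards_hei2015": hei2015_standards(),
        "standards_ahei2010": ahei2010_standards(),
        "agronomic": agronomic,
    }


def _generate_agronomic(
    commodities: pd.DataFrame, n_crops: int, rng: np.random.Generator
) -> AgronomicParameters:
    plant = commodities[~commodities["food_group"].isin(["dairy", "meat_poultry_fish"])]
    animal = commodities[commodities["food_group"].isin(["dairy", "meat_poultry_fish"])]

    # crops for plant groups, cycling so several commodities share a crop
    plant_groups = list(dict.fromkeys(plant["food_group"]))
    crop_rows = []
    crop_of_group: dict[str, list[str]] = {}
    yield_ranges = {
        "grains": (3000, 8000),
        "fruits": (10000, 30000),
        "vegetables": (15000, 40000),
        "legumes": (1500, 3000),
        "nuts": (2000, 4000),
        "sweeteners": (50000, 80000),
        "feed_grains_oilseeds": (4000, 9000),
    }
    i = 0
    while i < n_crops - 4:  # reserve 4 ids for feed/forage crops
        grp = plant_groups[i % len(plant_groups)]
        cat = _PLANT_GROUP_TO_CATEGORY[grp]
        lo, hi = yield_ranges[cat]
        crop_id = f"crop_{i:02d}_{cat}"
        crop_rows.append(
            {
                "crop_id": crop_id,
                "land_use_category": cat,
                "yield_kg_per_ha": float(rng.uniform(lo, hi)),
                "double_crop_factor": float(rng.uniform(1.0, 1.5))
                if cat == "vegetables"
                else 1.0,
                "utilization": 1.0,
            }
        )
        crop_of_group.setdefault(grp, []).append(crop_id)
        i += 1
    for crop_id, cat, yld, util in [
        ("feed_grain", "feed_grains_oilseeds", rng.uniform(4000, 9000), 1.0),
        ("hay", "hay", rng.uniform(6000, 12000), 1.0),
        ("cropland_forage", "cropland_pasture", rng.uniform(3000, 7000), 0.6),
        ("permanent_forage", "permanent_pasture", rng.uniform(2000, 6000), 0.5),
    ]:
        crop_rows.append(
            {
                "crop_id": crop_id,
                "land_use_category": cat,
                "yield_kg_per_ha": float(yld),
                "double_crop_factor": 1.0,
                "utilization": util,
            }
        )
    crop_table = pd.DataFrame(crop_rows)

    # commodity table: plants map to a group crop; animals to products.
    # at least one fruit/nut commodity is flagged non-domestic.
    ct_rows = []
    flagged = 0
    for _, row in commodities.iterrows():
        grp = row["food_group"]
        if grp in ("dairy", "meat_poultry_fish"):
            product = "milk" if grp == "dairy" else _ANIMAL_PRODUCTS[
                1 + int(rng.integers(0, 3))
            ]
            ct_rows.append(
                {
                    "commodity_id": row["commodity_id"],
                    "food_group": grp,
                    "kind": "animal",
                    "target_id": product,
                    "conversion": float(rng.uniform(0.9, 1.5)),
                    "allocation_fraction": 1.0,
                    "domestic": True,
                }
            )
        else:
            options = crop_of_group.get(grp) or [crop_table["crop_id"].iloc[0]]
            crop_id = options[int(rng.integers(0, len(options)))]
            domestic = True
            if grp in ("fruits", "nuts_seeds_legumes") and flagged < 1:
                domestic = False  # e.g. bananas / some nuts: not grown here
                flagged += 1
            ct_rows.append(
                {
                    "commodity_id": row["commodity_id"],
                    "food_group": grp,
                    "kind": "plant",
                    "target_id": crop_id,
                    "conversion": float(rng.uniform(0.7, 1.6)),
                    "allocation_fraction": np.nan,  # filled after sharing known
                    "domestic": domestic,
                }
            )
    commodity_table = pd.DataFrame(ct_rows)

    # feed vectors per livestock product (kg feed per kg carcass)
    feed_specs = {
        "milk": {"feed_grain": 0.5, "hay": 1.2, "cropland_forage": 0.3, "permanent_forage": 0.5},
        "beef": {"feed_grain": 2.5, "hay": 3.0, "permanent_forage": 6.0},
        "pork": {"feed_grain": 3.5},
        "chicken": {"feed_grain": 2.2, "cropland_forage": 0.1},
    }
    feed_rows = []
    used_products = set(
        commodity_table.loc[commodity_table["kind"] == "animal", "target_id"]
    )
    for product in used_products:
        for crop_id, base in feed_specs[product].items():
            feed_rows.append(
                {
                    "product_id": product,
                    "crop_id": crop_id,
                    "kg_per_kg": float(base * rng.uniform(0.8, 1.2)),
                    "allocation_fraction": np.nan,
                }
            )
    feed_table = pd.DataFrame(feed_rows)

    # allocation fractions: every user of a crop gets a Dirichlet share
    plant_users = commodity_table["kind"] == "plant"
    users = pd.concat(
        [
            commodity_table.loc[plant_users, ["target_id"]]
            .rename(columns={"target_id": "crop_id"})
            .assign(table="commodity", row=commodity_table.index[plant_users]),
            feed_table[["crop_id"]].assign(table="feed", row=feed_table.index),
        ],
        ignore_index=True,
    )
    for crop_id, sub in users.groupby("crop_id"):
        k = len(sub)
        fracs = np.full(k, 1.0 / k) if k == 1 else rng.dirichlet(np.full(k, 4.0))
        fracs = fracs / fracs.sum()
        for (_, rec), fr in zip(sub.iterrows(), fracs):
            if rec["table"] == "commodity":
                commodity_table.loc[rec["row"], "allocation_fraction"] = fr
            else:
                feed_table.loc[rec["row"], "allocation_fraction"] = fr

    rate_base = {
        "grains": (120, 50, 60, 2.5, 500),
        "fruits": (80, 40, 80, 15.0, 4000),
        "vegetables": (150, 60, 90, 8.0, 3000),
        "legumes": (10, 30, 40, 1.5, 400),
        "nuts": (120, 40, 80, 10.0, 6000),
        "sweeteners": (120, 50, 100, 4.0, 2000),
        "feed_grains_oilseeds": (140, 55, 70, 2.5, 700),
        "hay": (60, 25, 40, 0.5, 1500),
        "cropland_pasture": (20, 10, 10, 0.1, 100),
        "permanent_pasture": (5, 2, 2, 0.05, 20),
    }
    rate_rows = []
    for cat, (n, p, k, pest, irr) in rate_base.items():
        jitter = rng.uniform(0.85, 1.15, 5)
        rate_rows.append(
            {
                "land_use_category": cat,
                "n_kg_ha": n * jitter[0],
                "p2o5_kg_ha": p * jitter[1],
                "k2o_kg_ha": k * jitter[2],
                "pesticide_kg_ha": pest * jitter[3],
                "irrigation_m3_ha": irr * jitter[4],
            }
        )
    rates = pd.DataFrame(rate_rows)

    params = AgronomicParameters(
        commodity_table=commodity_table,
        feed_table=feed_table,
        crop_table=crop_table,
        rates=rates,
    )
    params.validate()
    return params


def _food_loadings(n_foods: int, recipes: pd.DataFrame, commodities: pd.DataFrame) -> np.ndarray:
    """Healthfulness loading per food = recipe-weighted commodity loading."""
    loading_by_commodity = commodities.set_index("commodity_id")["loading"]
    merged = recipes.assign(
        loading=loading_by_commodity.reindex(recipes["commodity_id"]).to_numpy()
    )
    per_food = merged.groupby("food_id").apply(
        lambda g: float(np.sum(g["fraction"] * g["loading"])), include_groups=False
    )
    out = np.zeros(n_foods)
    for i in range(n_foods):
        out[i] = per_food.get(f"F{i:03d}", 0.0)
    return out


def generate_population(
    design: SurveyDesignSpec,
    pop: PopulationSpec,
    tables: dict | None = None,
) -> pd.DataFrame:
    """Generate one dietary record per simulated individual.

    Returns a DataFrame with design variables (stratum, psu, weight),
    demographics, energy, per-food gram intakes (``food_<id>_g``), and the
    raw per-day index-component amounts the scoring standards reference.
    Deterministic for a given ``design.seed``.
    """
    if tables is None:
        tables = generate_parameter_tables(
            pop.n_foods,
            pop.n_commodities,
            seed=design.seed,
            unmapped_food_fraction=pop.unmapped_food_fraction,
        )
    rng = np.random.default_rng(design.seed)
    n = design.n_individuals

    strata = np.repeat(np.arange(1, design.n_strata + 1), design.psus_per_stratum * design.individuals_per_psu)
    psus = np.tile(
        np.repeat(np.arange(1, design.psus_per_stratum + 1), design.individuals_per_psu),
        design.n_strata,
    )
    weights = rng.lognormal(design.weight_log_mean, design.weight_log_sd, n)
    age = rng.uniform(pop.age_min, pop.age_max, n)
    sex = np.where(rng.random(n) < pop.sex_male_fraction, "male", "female")

    # energy first; a small PSU-level shift induces intra-cluster correlation
    psu_effect = rng.normal(0.0, 0.06, design.n_strata * design.psus_per_stratum)
    psu_index = (strata - 1) * design.psus_per_stratum + (psus - 1)
    energy = rng.normal(pop.energy_mean, pop.energy_sd, n) * (1 + psu_effect[psu_index])
    energy = np.maximum(energy, pop.energy_floor)

    h = rng.normal(0.0, 1.0, n)  # latent healthfulness

    records = pd.DataFrame(
        {
            "person_id": [f"P{i:05d}" for i in range(n)],
            "stratum": strata,
            "psu": psus,
            "weight": weights,
            "age": age,
            "sex": sex,
            "energy_kcal": energy,
        }
    )

    g = pop.gradient

    def adequacy_density(full: float, scale: float = 1.0) -> np.ndarray:
        lvl = 0.55 + 0.28 * np.tanh(g * h) + 0.18 * rng.normal(size=n)
        return np.clip(lvl, 0.0, None) * full * scale

    def moderation_amount(zero: float, full: float) -> np.ndarray:
        # healthier individuals sit closer to the full-score (low) threshold
        lvl = 0.5 - 0.3 * np.tanh(g * h) + 0.18 * rng.normal(size=n)
        return np.clip(full + np.clip(lvl, 0.0, None) * (zero - full) * 1.4, 0.0, None)

    e_scale = energy / 1000.0
    # HEI-2015 raw amounts (absolute per day, densities times energy)
    records["fruit_total_cup"] = adequacy_density(0.8) * e_scale
    records["fruit_whole_cup"] = np.minimum(
        adequacy_density(0.4) * e_scale, records["fruit_total_cup"]
    )
    records["veg_total_cup"] = adequacy_density(1.1) * e_scale
    records["greens_beans_cup"] = np.minimum(
        adequacy_density(0.2) * e_scale, records["veg_total_cup"]
    )
    records["whole_grains_oz"] = adequacy_density(1.5) * e_scale
    records["dairy_cup"] = adequacy_density(1.3) * e_scale
    records["protein_total_oz"] = adequacy_density(2.5) * e_scale
    records["protein_seafood_plant_oz"] = np.minimum(
        adequacy_density(0.8) * e_scale, records["protein_total_oz"]
    )
    records["refined_grains_oz"] = moderation_amount(4.3, 1.8) * e_scale
    records["sodium_g"] = moderation_amount(2.0, 1.1) * e_scale
    sat_pct = moderation_amount(16.0, 8.0)  # % of energy
    records["sat_fat_g"] = sat_pct / 100.0 * energy / 9.0
    ratio = adequacy_density(2.5) + 0.4  # unsat:sat target ratio
    records["unsat_fat_g"] = ratio * records["sat_fat_g"]
    sugar_pct = moderation_amount(26.0, 6.5)
    records["added_sugar_g"] = sugar_pct / 100.0 * energy / 4.0

    # AHEI-2010 raw amounts (absolute per day; generated on the 1849 basis)
    a_scale = energy / 1849.0
    records["veg_servings"] = adequacy_density(5.0) * a_scale
    records["fruit_servings"] = adequacy_density(4.0) * a_scale
    records["whole_grains_g"] = records["whole_grains_oz"] * 28.35
    records["nuts_legumes_servings"] = adequacy_density(1.0) * a_scale
    records["omega3_mg"] = adequacy_density(250.0) * a_scale
    pufa_pct = np.clip(2.0 + adequacy_density(8.0), 0.0, None)
    records["pufa_g"] = pufa_pct / 100.0 * energy / 9.0
    records["ssb_juice_servings"] = moderation_amount(1.0, 0.0) * a_scale
    records["red_meat_servings"] = moderation_amount(1.5, 0.0) * a_scale
    adult = age >= 18
    drinks = np.where(
        rng.random(n) < 0.45, 0.0, rng.lognormal(-0.7, 0.8, n)
    )
    child_drinks = np.where(rng.random(n) < 0.03, rng.uniform(0.1, 1.0, n), 0.0)
    records["alcohol_drinks"] = np.where(adult, drinks, child_drinks)

    # per-food grams: total mass tied to energy, shares tilted by loading
    density = rng.uniform(1.1, 2.2, n)  # kcal per gram of the whole diet
    total_g = energy / density
    loadings = _food_loadings(pop.n_foods, tables["recipes"], _commodity_frame(pop.n_commodities))
    base_share = rng.dirichlet(np.full(pop.n_foods, 2.0))
    share_noise = rng.normal(0.0, 0.25, (n, pop.n_foods))
    logit = (
        np.log(base_share)[None, :]
        + g * np.outer(h, loadings)
        + share_noise
    )
    shares = np.exp(logit)
    shares /= shares.sum(axis=1, keepdims=True)
    grams = shares * total_g[:, None]
    for j in range(pop.n_foods):
        records[f"food_F{j:03d}_g"] = grams[:, j]

    return records


def write_inputs(
    outdir,
    records: pd.DataFrame,
    tables: dict,
    design: SurveyDesignSpec,
    pop: PopulationSpec,
) -> dict[str, str]:
    """Write the five input tables as CSV plus the generation spec as YAML."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    records.to_csv(out / "recall.csv", index=False)
    paths["recall"] = str(out / "recall.csv")
    tables["recipes"].to_csv(out / "recipes.csv", index=False)
    paths["recipes"] = str(out / "recipes.csv")
    tables["loss_profiles"].to_csv(out / "loss_profiles.csv", index=False)
    paths["loss_profiles"] = str(out / "loss_profiles.csv")
    tables["standards_hei2015"].to_csv(out / "standards_hei2015.csv", index=False)
    paths["standards_hei2015"] = str(out / "standards_hei2015.csv")
    tables["standards_ahei2010"].to_csv(out / "standards_ahei2010.csv", index=False)
    paths["standards_ahei2010"] = str(out / "standards_ahei2010.csv")
    ag = tables["agronomic"]
    for name, df in [
        ("commodity_table", ag.commodity_table),
        ("feed_table", ag.feed_table),
        ("crop_table", ag.crop_table),
        ("application_rates", ag.rates),
    ]:
        df.to_csv(out / f"{name}.csv", index=False)
        paths[name] = str(out / f"{name}.csv")
    spec = {
        "design": {
            "n_strata": design.n_strata,
            "psus_per_stratum": design.psus_per_stratum,
            "individuals_per_psu": design.individuals_per_psu,
            "weight_log_mean": design.weight_log_mean,
            "weight_log_sd": design.weight_log_sd,
            "seed": design.seed,
        },
        "population": {
            "n_foods": pop.n_foods,
            "n_commodities": pop.n_commodities,
            "energy_mean": pop.energy_mean,
            "energy_sd": pop.energy_sd,
            "energy_floor": pop.energy_floor,
            "gradient": pop.gradient,
            "age_min": pop.age_min,
            "age_max": pop.age_max,
            "sex_male_fraction": pop.sex_male_fraction,
            "unmapped_food_fraction": pop.unmapped_food_fraction,
        },
    }
    with open(out / "generation_spec.yaml", "w") as fh:
        yaml.safe_dump(spec, fh)
    paths["spec"] = str(out / "generation_spec.yaml")
    return paths
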