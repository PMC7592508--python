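"""Simplified closed-food-system biophysical model ("foodprint").

Population food demand (g/d per capita, by commodity) is converted into the
agricultural land and inputs needed to produce it under the assumption that
everything consumed is grown domestically:

1. demand for commodities not produced domestically is reapportioned to the
   remaining commodities of the same food group, proportional to their mass;
2. plant commodities are converted to primary crop mass (the processing
   conversion embeds pre-retail losses such as moisture and milling loss);
   animal commodities are converted to carcass weight and then, via a feed
   requirement vector, to feed-crop and forage mass by livestock category;
3. shared (multi-use) crops carry allocation fractions: each use is charged
   its gross crop draw times its allocated share, so joint-product crops
   are never double counted and total allocated mass equals total demanded
   mass exactly;
4. crop mass becomes land through yields, double-crop factors (land used
   for more than one crop per year) and, for grazed categories, a forage
   utilization scalar; land becomes fertilizer nutrients (N + P2O5 + K2O),
   pesticides, and irrigation water through per-hectare application rates.

The chain is linear in demand, so footprints computed separately for the
retail-loss, inedible, consumer-waste, and consumed streams add up to the
footprint of Total Food Demand; their shares attribute resource use to each
stream.  Monte Carlo uncertainty comes from weighted non-replacement draws
of individuals, re-running the whole chain per draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EstimationError, ModelError

LAND_USE_CATEGORIES = [
    "grains",
    "fruits",
    "vegetables",
    "legumes",
    "nuts",
    "sweeteners",
    "feed_grains_oilseeds",
    "hay",
    "cropland_pasture",
    "permanent_pasture",
]

RESOURCE_COLUMNS = ["land_ha", "fertilizer_kg", "pesticide_kg", "irrigation_m3"]

DAYS_PER_YEAR = 365.25


@dataclass
class AgronomicParameters:
    """Parameter tables driving the demand-to-resources chain.

    commodity_table: commodity_id, food_group, kind (plant|animal),
        target_id (crop for plants, livestock product for animals),
        conversion (kg primary crop or carcass per kg as-consumed food),
        allocation_fraction (share of the shared target crop's mass
        attributed to this chain; sums to 1 per multi-use crop),
        domestic (bool).
    feed_table: product_id, crop_id, kg_per_kg (kg feed crop or forage per
        kg carcass), allocation_fraction.
    crop_table: crop_id, land_use_category, yield_kg_per_ha,
        double_crop_factor (>= 1), utilization (grazed-forage utilization,
        in (0, 1]).
    rates: land_use_category, n_kg_ha, p2o5_kg_ha, k2o_kg_ha,
        pesticide_kg_ha, irrigation_m3_ha.
    available_land: optional land_use_category -> hectares available.
    """

    commodity_table: pd.DataFrame
    feed_table: pd.DataFrame
    crop_table: pd.DataFrame
    rates: pd.DataFrame
    available_land: pd.Series | None = None

    def validate(self) -> None:
        ct = self.commodity_table
        if (ct["conversion"] <= 0).any():
            raise ConfigurationError("processing conversions must be > 0")
        if not ct["kind"].isin(["plant", "animal"]).all():
            raise ConfigurationError("commodity kind must be plant or animal")
        cr = self.crop_table
        if (cr["yield_kg_per_ha"] <= 0).any():
            raise ConfigurationError("yields must be > 0")
        if (cr["double_crop_factor"] < 1).any():
            raise ConfigurationError("double-crop factors must be >= 1")
        if ((cr["utilization"] <= 0) | (cr["utilization"] > 1)).any():
            raise ConfigurationError("utilization must lie in (0, 1]")
        if not cr["land_use_category"].isin(LAND_USE_CATEGORIES).all():
            bad = sorted(set(cr["land_use_category"]) - set(LAND_USE_CATEGORIES))
            raise ConfigurationError(f"unknown land-use categories {bad}")
        rate_cols = ["n_kg_ha", "p2o5_kg_ha", "k2o_kg_ha", "pesticide_kg_ha", "irrigation_m3_ha"]
        if (self.rates[rate_cols] < 0).to_numpy().any():
            raise ConfigurationError("application rates must be >= 0")
        # allocation fractions must sum to 1 per shared crop across its users
        users = pd.concat(
            [
                ct.loc[ct["kind"] == "plant", ["target_id", "allocation_fraction"]].rename(
                    columns={"target_id": "crop_id"}
                ),
                self.feed_table[["crop_id", "allocation_fraction"]],
            ]
        )
        sums = users.groupby("crop_id")["allocation_fraction"].sum()
        bad = sums[(sums - 1.0).abs() > 1e-9]
        if not bad.empty:
            raise ConfigurationError(
                f"allocation fractions do not sum to 1 for crops {bad.index.tolist()}"
            )


@dataclass
class ResourceFootprint:
    """Land and input use by land-use category, population scale per year."""

    by_category: pd.DataFrame  # index land_use_category, columns RESOURCE_COLUMNS

    @property
    def totals(self) -> pd.Series:
        return self.by_category.sum(axis=0)

    def __add__(self, other: "ResourceFootprint") -> "ResourceFootprint":
        return ResourceFootprint(self.by_category.add(other.by_category, fill_value=0.0))

    def scaled(self, k: float) -> "ResourceFootprint":
        return ResourceFootprint(self.by_category * k)


def reapportion_imports(demand: pd.DataFrame, commodity_table: pd.DataFrame) -> pd.DataFrame:
    """Redistribute demand for non-domestic commodities within food group.

    ``demand`` is a (commodity_id, kg) table.  Mass of commodities flagged
    ``domestic == False`` is moved to the group's domestic members
    proportional to their demand (equally when all domestic demand is zero);
    group totals are conserved exactly.
    """
    ct = commodity_table.set_index("commodity_id")
    missing = set(demand["commodity_id"]) - set(ct.index)
    if missing:
        raise ConfigurationError(f"commodities missing from commodity table: {sorted(missing)}")
    df = demand.copy()
    df["food_group"] = ct.reindex(df["commodity_id"])["food_group"].to_numpy()
    df["domestic"] = ct.reindex(df["commodity_id"])["domestic"].to_numpy().astype(bool)
    out_rows = []
    for grp, sub in df.groupby("food_group", sort=False):
        dom = sub[sub["domestic"]]
        imp = sub[~sub["domestic"]]
        moved = float(imp["kg"].sum())
        if moved > 0 and dom.empty:
            raise ModelError(f"food group {grp!r} has demand but no domestic commodity")
        if moved > 0:
            base = dom["kg"].to_numpy(dtype=float)
            share = base / base.sum() if base.sum() > 0 else np.full(len(dom), 1.0 / len(dom))
            dom = dom.assign(kg=base + moved * share)
        out_rows.append(dom.assign(kg=dom["kg"]))
        if not imp.empty:
            out_rows.append(imp.assign(kg=0.0))
    out = pd.concat(out_rows)[["commodity_id", "kg"]]
    return out.sort_values("commodity_id", kind="mergesort").reset_index(drop=True)


def demand_to_primary_crops(
    demand: pd.DataFrame, params: AgronomicParameters
) -> tuple[pd.Series, pd.DataFrame]:
    """Convert commodity demand (kg/yr) into primary crop requirements.

    Returns ``(requirements, ledger)``: requirements are kg/yr per crop_id;
    the ledger records, per (crop, user), the gross crop draw
    (demand / allocation fraction, i.e. the crop mass that passes through
    the chain) and the allocated share actually charged, whose sum over
    users equals the demanded primary mass exactly.
    """
    params.validate()
    ct = params.commodity_table.set_index("commodity_id")
    missing = set(demand["commodity_id"]) - set(ct.index)
    if missing:
        raise ConfigurationError(f"no conversion for commodities {sorted(missing)}")
    ledger_rows = []
    for _, row in demand.iterrows():
        cinfo = ct.loc[row["commodity_id"]]
        primary = float(row["kg"]) * float(cinfo["conversion"])
        if cinfo["kind"] == "plant":
            a = float(cinfo["allocation_fraction"])
            ledger_rows.append(
                {
                    "crop_id": cinfo["target_id"],
                    "user": row["commodity_id"],
                    "gross_draw_kg": primary / a,
                    "allocation_fraction": a,
                    "allocated_kg": primary,
                }
            )
        else:
            feeds = params.feed_table[params.feed_table["product_id"] == cinfo["target_id"]]
            if feeds.empty:
                raise ConfigurationError(
                    f"no feed vector for livestock product {cinfo['target_id']!r}"
                )
            for _, f in feeds.iterrows():
                need = primary * float(f["kg_per_kg"])
                a = float(f["allocation_fraction"])
                ledger_rows.append(
                    {
                        "crop_id": f["crop_id"],
                        "user": f"{row['commodity_id']}:{cinfo['target_id']}",
                        "gross_draw_kg": need / a,
                        "allocation_fraction": a,
                        "allocated_kg": need,
                    }
                )
    ledger = pd.DataFrame(ledger_rows)
    requirements = ledger.groupby("crop_id")["allocated_kg"].sum()
    unknown = set(requirements.index) - set(params.crop_table["crop_id"])
    if unknown:
        raise ConfigurationError(f"feed/crop ids missing from crop table: {sorted(unknown)}")
    return requirements, ledger


def crops_to_land(requirements: pd.Series, params: AgronomicParameters) -> pd.Series:
    """Land (ha/yr) by land-use category from crop requirements (kg/yr)."""
    cr = params.crop_table.set_index("crop_id")
    missing = set(requirements.index) - set(cr.index)
    if missing:
        raise ConfigurationError(f"crops missing from crop table: {sorted(missing)}")
    sub = cr.reindex(requirements.index)
    if (sub["yield_kg_per_ha"] <= 0).any():
        raise ConfigurationError("zero or negative yield")
    land = requirements / (
        sub["yield_kg_per_ha"] * sub["utilization"] * sub["double_crop_factor"]
    )
    by_cat = land.groupby(sub["land_use_category"]).sum()
    return by_cat.reindex(LAND_USE_CATEGORIES, fill_value=0.0)


def land_to_resources(
    land_by_category: pd.Series, params: AgronomicParameters
) -> ResourceFootprint:
    """Apply per-hectare application rates to land by category."""
    rates = params.rates.set_index("land_use_category")
    nonzero = land_by_category[land_by_category > 0]
    missing = set(nonzero.index) - set(rates.index)
    if missing:
        raise ConfigurationError(f"no application rates for categories {sorted(missing)}")
    r = rates.reindex(land_by_category.index).fillna(0.0)
    df = pd.DataFrame(index=land_by_category.index)
    df["land_ha"] = land_by_category
    df["fertilizer_kg"] = land_by_category * (
        r["n_kg_ha"] + r["p2o5_kg_ha"] + r["k2o_kg_ha"]
    )
    df["pesticide_kg"] = land_by_category * r["pesticide_kg_ha"]
    df["irrigation_m3"] = land_by_category * r["irrigation_m3_ha"]
    df.index.name = "land_use_category"
    return ResourceFootprint(df)


def footprint_from_demand(
    per_capita_g_per_day: pd.Series,
    params: AgronomicParameters,
    population: float,
) -> ResourceFootprint:
    """Run the full chain for one demand stream.

    ``per_capita_g_per_day`` is indexed by commodity_id.  Output is at
    population scale per year (ha/yr, kg/yr, m3/yr).
    """
    if population <= 0:
        raise ConfigurationError("population must be positive")
    demand = pd.DataFrame(
        {
            "commodity_id": per_capita_g_per_day.index,
            "kg": per_capita_g_per_day.to_numpy(dtype=float)
            * population
            * DAYS_PER_YEAR
            / 1000.0,
        }
    )
    demand = reapportion_imports(demand, params.commodity_table)
    requirements, _ = demand_to_primary_crops(demand, params)
    land = crops_to_land(requirements, params)
    return land_to_resources(land, params)


def attribute_to_loss_categories(
    footprints: dict[str, ResourceFootprint]
) -> pd.DataFrame:
    """Share of each resource total attributable to each demand stream.

    ``footprints`` maps stream name (retail_loss, inedible, consumer_waste,
    consumed) to the footprint obtained by running the model on that stream
    alone.  Shares sum to 1 per resource.
    """
    totals = pd.DataFrame({name: fp.totals for name, fp in footprints.items()}).T
    denom = totals.sum(axis=0)
    zero = denom[denom == 0]
    if not zero.empty:
        raise EstimationError(f"all-zero resource(s) {zero.index.tolist()}: share undefined")
    return totals / denom


def check_land_availability(
    footprint: ResourceFootprint, available_land: pd.Series
) -> pd.DataFrame:
    """Report required vs available land by class with an exceedance flag."""
    req = footprint.by_category["land_ha"]
    avail = available_land.reindex(req.index)
    return pd.DataFrame(
        {"required_ha": req, "available_ha": avail, "exceeds": req > avail}
    )


def monte_carlo_footprint(
    person_demand: pd.DataFrame,
    weights: pd.Series,
    params: AgronomicParameters,
    population: float,
    *,
    draw_size: int | None = None,
    n_reps: int = 500,
    seed: int = 0,
    weighted_draws: bool = True,
) -> dict:
    """Monte Carlo footprint uncertainty from inter-individual variability.

    ``person_demand`` is a long (person_id, commodity_id, grams) table of
    the demand stream; each replicate draws ``draw_size`` individuals
    without replacement (probability proportional to survey weight by
    default), recomputes the weighted per-capita demand and the full model
    chain, and scales to the population.  Returns the replicate matrix, the
    mean, and 2.5/97.5 percentile bounds per resource.
    """
    w = pd.Series(weights, dtype=float)
    n = w.size
    if draw_size is None:
        draw_size = max(2, n // 2)  # half-sample default
    if draw_size > n:
        raise EstimationError(f"draw_size {draw_size} exceeds n={n}")
    if n_reps < 2:
        raise EstimationError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    ids = w.index.to_numpy()
    probs = (w / w.sum()).to_numpy() if weighted_draws else None
    wide = person_demand.pivot_table(
        index="person_id", columns="commodity_id", values="grams", aggfunc="sum", fill_value=0.0
    ).reindex(w.index, fill_value=0.0)
    reps = []
    for _ in range(n_reps):
        chosen = rng.choice(ids, size=draw_size, replace=False, p=probs)
        sub_w = w.loc[chosen]
        per_capita = wide.loc[chosen].mul(sub_w, axis=0).sum() / sub_w.sum()
        fp = footprint_from_demand(per_capita, params, population)
        reps.append(fp.totals)
    rep_df = pd.DataFrame(reps)
    return {
        "replicates": rep_df,
        "mean": rep_df.mean(axis=0),
        "ci_low": rep_df.quantile(0.025, axis=0),
        "ci_high": rep_df.quantile(0.975, axis=0),
        "n_reps": n_reps,
        "draw_size": draw_size,
    }
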