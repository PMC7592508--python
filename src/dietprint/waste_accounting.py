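"""Food loss and waste mass-balance accounting.

Observed intake is consumed mass; commodity-level loss fractions (retail
loss, inedible portion, consumer waste) are forward rates.  The accounting
therefore runs backward: consumed mass is divided through the sequential
loss chain to recover the edible purchased, purchased, and retail-level
(Total Food Demand) masses, and the loss-category masses fall out by
subtraction:

    edible_purchased = consumed / (1 - w)       w: consumer-waste fraction
    purchased        = edible_purchased / (1 - i)   i: inedible fraction
    total_demand     = purchased / (1 - r)      r: retail-loss fraction

Total Food Demand = consumed + consumer waste + inedible + retail loss by
construction, at every aggregation scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EstimationError

CATEGORY_COLUMNS = [
    "consumed",
    "consumer_waste",
    "inedible",
    "edible_purchased",
    "purchased",
    "retail_loss",
    "total_demand",
]

#: the four additive loss/waste streams making up Total Food Demand
LOSS_STREAMS = ["retail_loss", "inedible", "consumer_waste", "consumed"]


@dataclass(frozen=True)
class CommodityLossProfile:
    """Per-commodity loss fractions: retail loss (of retail supply),
    inedible (of purchased mass), consumer waste (of edible purchased)."""

    commodity_id: str
    retail_loss_fraction: float
    inedible_fraction: float
    consumer_waste_fraction: float

    def __post_init__(self) -> None:
        for name in ("retail_loss_fraction", "inedible_fraction", "consumer_waste_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(
                    f"{self.commodity_id}: {name}={v} outside [0, 1)"
                )


@dataclass(frozen=True)
class DemandBreakdown:
    """Mass (g/d) in each loss/waste category for one scope."""

    consumed: float
    consumer_waste: float
    inedible: float
    edible_purchased: float
    purchased: float
    retail_loss: float
    total_demand: float

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in CATEGORY_COLUMNS}


def partition_commodity(consumed_g: float, profile: CommodityLossProfile) -> DemandBreakdown:
    """Back-calculate the full demand breakdown for one commodity mass."""
    if consumed_g < 0 or not np.isfinite(consumed_g):
        raise ValueError(f"consumed mass must be finite and >= 0, got {consumed_g}")
    w = profile.consumer_waste_fraction
    i = profile.inedible_fraction
    r = profile.retail_loss_fraction
    edible = consumed_g / (1.0 - w)
    purchased = edible / (1.0 - i)
    total = purchased / (1.0 - r)
    return DemandBreakdown(
        consumed=consumed_g,
        consumer_waste=edible - consumed_g,
        inedible=purchased - edible,
        edible_purchased=edible,
        purchased=purchased,
        retail_loss=total - purchased,
        total_demand=total,
    )


def partition_intakes(
    intakes: pd.DataFrame,
    loss_profiles: pd.DataFrame,
    *,
    missing_policy: str = "zero",
) -> pd.DataFrame:
    """Vectorized breakdown of a long (person_id, commodity_id, grams) table.

    Commodities absent from the loss table get zero loss with a warning
    under the default policy, or raise under ``missing_policy='error'``.
    Returns the intake table with the seven category columns appended.
    """
    if missing_policy not in {"zero", "error"}:
        raise ConfigurationError(f"unknown missing_policy {missing_policy!r}")
    prof = loss_profiles.set_index("commodity_id")
    for col in ("retail_loss_fraction", "inedible_fraction", "consumer_waste_fraction"):
        vals = prof[col]
        if ((vals < 0) | (vals >= 1)).any():
            bad = prof.index[(vals < 0) | (vals >= 1)].tolist()
            raise ConfigurationError(f"loss fractions outside [0,1) for {bad}")
    missing = set(intakes["commodity_id"]) - set(prof.index)
    if missing:
        if missing_policy == "error":
            raise ConfigurationError(f"no loss profile for commodities {sorted(missing)}")
        warnings.warn(
            f"assigning zero loss to {len(missing)} commodity(ies) missing from the "
            f"loss table: {sorted(missing)}"
        )
    out = intakes.copy()
    frac = prof.reindex(out["commodity_id"]).fillna(0.0)
    w = frac["consumer_waste_fraction"].to_numpy()
    i = frac["inedible_fraction"].to_numpy()
    r = frac["retail_loss_fraction"].to_numpy()
    consumed = out["grams"].to_numpy(dtype=float)
    edible = consumed / (1.0 - w)
    purchased = edible / (1.0 - i)
    total = purchased / (1.0 - r)
    out["consumed"] = consumed
    out["consumer_waste"] = edible - consumed
    out["inedible"] = purchased - edible
    out["edible_purchased"] = edible
    out["purchased"] = purchased
    out["retail_loss"] = total - purchased
    out["total_demand"] = total
    return out


def per_capita_breakdown(
    breakdowns: pd.DataFrame,
    weights: pd.Series,
    group_map: pd.Series | dict[str, str] | None = None,
) -> pd.DataFrame:
    """Survey-weighted per-capita means of every category, overall and by
    food group.

    ``breakdowns`` is the long per-person-commodity table from
    :func:`partition_intakes`; ``weights`` maps person_id -> survey weight;
    ``group_map`` maps commodity_id -> food group.  Returns one row per
    scope (``overall`` plus each group) with the category columns.
    """
    if breakdowns.empty:
        raise EstimationError("empty breakdown table")
    w_by_person = pd.Series(weights, dtype=float)
    if (w_by_person <= 0).any():
        raise EstimationError("weights must be strictly positive")
    df = breakdowns.copy()
    if group_map is not None:
        gm = pd.Series(group_map)
        missing = set(df["commodity_id"]) - set(gm.index)
        if missing:
            raise ConfigurationError(f"commodities missing from group map: {sorted(missing)}")
        df["food_group"] = gm.reindex(df["commodity_id"]).to_numpy()
    else:
        df["food_group"] = "all"

    wsum = float(w_by_person.sum())

    def _mean_rows(sub: pd.DataFrame) -> pd.Series:
        # per-person totals within the scope, then weighted mean over ALL
        # persons (individuals consuming nothing in the scope contribute 0)
        per_person = sub.groupby("person_id")[CATEGORY_COLUMNS].sum()
        per_person = per_person.reindex(w_by_person.index, fill_value=0.0)
        return per_person.mul(w_by_person, axis=0).sum() / wsum

    rows = {"overall": _mean_rows(df)}
    if group_map is not None:
        for grp, sub in df.groupby("food_group"):
            rows[grp] = _mean_rows(sub)
    out = pd.DataFrame(rows).T
    out.index.name = "scope"
    return out
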