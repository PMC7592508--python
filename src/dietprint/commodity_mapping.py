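"""Disaggregation of as-consumed foods into commodity-level intakes.

Mixed dishes reported on a dietary recall are split into their commodity
ingredients with a recipe table of mass fractions (the role the EPA Food
Commodity Intake Database plays for NHANES foods).  Foods absent from the
recipe table — the real crosswalk stops at 2010 food codes — are dropped
with a coverage report, or raise under the strict policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MappingError

FOOD_COL_PREFIX = "food_"
FOOD_COL_SUFFIX = "_g"


@dataclass(frozen=True)
class CoverageReport:
    """Which foods the recipe table could not map, and how much mass."""

    unmapped_foods: tuple[str, ...]
    unmapped_grams: float
    total_grams: float

    @property
    def mapped_grams(self) -> float:
        return self.total_grams - self.unmapped_grams

    @property
    def unmapped_share(self) -> float:
        """Unmapped mass as a share of total reported food mass (the
        all-food denominator); the mapped-only denominator is
        ``unmapped_grams / mapped_grams``."""
        return self.unmapped_grams / self.total_grams if self.total_grams > 0 else 0.0

    def as_dict(self) -> dict:
        return {
            "unmapped_foods": list(self.unmapped_foods),
            "unmapped_grams": self.unmapped_grams,
            "total_grams": self.total_grams,
            "mapped_grams": self.mapped_grams,
            "unmapped_share_of_total": self.unmapped_share,
            "unmapped_share_of_mapped": (
                self.unmapped_grams / self.mapped_grams if self.mapped_grams > 0 else 0.0
            ),
        }


def food_columns(records: pd.DataFrame) -> list[str]:
    """Per-food gram columns of a recall table (``food_<id>_g``)."""
    return [
        c
        for c in records.columns
        if c.startswith(FOOD_COL_PREFIX) and c.endswith(FOOD_COL_SUFFIX)
    ]


def food_id_from_column(col: str) -> str:
    return col[len(FOOD_COL_PREFIX) : -len(FOOD_COL_SUFFIX)]


def validate_recipes(recipes: pd.DataFrame, *, tol: float = 1e-6) -> None:
    """Recipe fractions must be >= 0, unique per (food, commodity), and sum
    to 1 per food within ``tol``.  Violations abort rather than silently
    renormalizing."""
    required = {"food_id", "commodity_id", "fraction"}
    if not required.issubset(recipes.columns):
        raise ConfigurationError(f"recipe table needs columns {sorted(required)}")
    if (recipes["fraction"] < 0).any():
        raise ConfigurationError("negative recipe fractions")
    dup = recipes.duplicated(subset=["food_id", "commodity_id"])
    if dup.any():
        raise ConfigurationError(
            f"duplicate (food, commodity) recipe rows: "
            f"{recipes.loc[dup, ['food_id', 'commodity_id']].to_records(index=False).tolist()}"
        )
    sums = recipes.groupby("food_id")["fraction"].sum()
    bad = sums[(sums - 1.0).abs() > tol]
    if not bad.empty:
        raise ConfigurationError(
            f"recipe fractions do not sum to 1 for foods {bad.index.tolist()}"
        )


def disaggregate(
    records: pd.DataFrame,
    recipes: pd.DataFrame,
    *,
    unmapped_policy: str = "drop",
    tol: float = 1e-6,
) -> tuple[pd.DataFrame, CoverageReport]:
    """Distribute each individual's food grams to commodities by recipe
    fraction.

    Returns a long table (person_id, commodity_id, grams) plus a coverage
    report for foods missing from the recipe table.  Under the default
    ``unmapped_policy='drop'`` their mass is excluded with a warning; under
    ``'error'`` the first unmapped food aborts the run by name.
    """
    if unmapped_policy not in {"drop", "error"}:
        raise ConfigurationError(f"unknown unmapped_policy {unmapped_policy!r}")
    validate_recipes(recipes, tol=tol)
    cols = food_columns(records)
    if not cols:
        raise ConfigurationError("recall table has no food_<id>_g columns")
    food_ids = [food_id_from_column(c) for c in cols]
    known = set(recipes["food_id"])
    unmapped = [f for f in food_ids if f not in known]
    if unmapped and unmapped_policy == "error":
        raise MappingError(f"no recipe for food id {unmapped[0]!r}")

    grams_wide = records.set_index("person_id")[cols]
    grams_wide.columns = food_ids
    if (grams_wide < 0).to_numpy().any():
        raise ConfigurationError("negative food gram intakes")
    total_g = float(grams_wide.to_numpy().sum())
    unmapped_g = float(grams_wide[unmapped].to_numpy().sum()) if unmapped else 0.0
    report = CoverageReport(
        unmapped_foods=tuple(unmapped), unmapped_grams=unmapped_g, total_grams=total_g
    )
    if unmapped:
        warnings.warn(
            f"dropping {len(unmapped)} unmapped food(s) "
            f"({100 * report.unmapped_share:.1f}% of reported food mass)"
        )

    long = grams_wide.reset_index().melt(
        id_vars="person_id", var_name="food_id", value_name="food_grams"
    )
    merged = long.merge(recipes, on="food_id", how="inner")
    merged["grams"] = merged["food_grams"] * merged["fraction"]
    out = (
        merged.groupby(["person_id", "commodity_id"], as_index=False, sort=True)["grams"]
        .sum()
        .sort_values(["person_id", "commodity_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out, report


def aggregate_to_food_groups(
    intakes: pd.DataFrame, group_map: pd.Series | dict[str, str]
) -> pd.DataFrame:
    """Sum commodity intakes to per-individual food-group totals.

    Every commodity must belong to exactly one group; mass is conserved
    exactly.  Returns a long table (person_id, food_group, grams).
    """
    gm = pd.Series(group_map)
    missing = set(intakes["commodity_id"]) - set(gm.index)
    if missing:
        raise ConfigurationError(f"commodities missing from group map: {sorted(missing)}")
    df = intakes.copy()
    df["food_group"] = gm.reindex(df["commodity_id"]).to_numpy()
    return (
        df.groupby(["person_id", "food_group"], as_index=False, sort=True)["grams"]
        .sum()
        .reset_index(drop=True)
    )
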