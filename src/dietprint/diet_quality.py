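"""Diet-quality index scoring: HEI-2015 and (modified) AHEI-2010.

Both indices score a set of components on piecewise-linear standards and sum
them to a 0-100 total.  HEI-2015 expresses most components as densities per
1000 kcal (the density method); the modified AHEI-2010 rescales absolute
daily amounts to a 1849 kcal/d basis (the mean energy intake of the source
population from which the index was derived) so that children and adults are
scored on a common footing.  Scoring standards are data, not code: they ship
as editable CSV tables (see ``dietprint/data``) so that variants such as the
unmodified AHEI-2010 are a table/flag swap rather than a code change.

Population mean scores use the population-ratio method: each component's
*population* density (ratio of weighted total intake to weighted total
energy, scaled to the component basis) is scored once, and the component
scores are summed.  This is not the weighted mean of individual scores —
clamping at 0 and at the component maximum makes the two differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EstimationError, ScoringError

AHEI_REFERENCE_KCAL = 1849.0  # mean energy intake of the AHEI source population
DENSITY_BASIS_KCAL = 1000.0

_STANDARD_FILES = {
    "hei2015": "hei2015_standards.csv",
    "ahei2010": "ahei2010_standards.csv",
}


@dataclass(frozen=True)
class ScoringStandard:
    """One component's scoring rule.

    ``zero_score`` and ``full_score`` are the intake amounts (on the
    component basis) awarded 0 and ``max_points`` points; between them the
    score is linearly interpolated and outside them it is clamped.  For
    adequacy components ``full_score > zero_score``; moderation components
    are reverse scored (``full_score < zero_score``).  ``alcohol_band``
    replaces the two-threshold rule with a two-sided trapezoid plus an
    abstainer credit.
    """

    component: str
    index: str
    amount_column: str
    direction: str
    max_points: float
    zero_score: float
    full_score: float
    basis: str
    denominator_column: str | None = None
    energy_per_unit: float | None = None
    special_rule: str = "none"
    band_full_low: float | None = None
    band_full_high: float | None = None
    band_zero_high: float | None = None
    abstainer_points: float | None = None

    def __post_init__(self) -> None:
        if self.max_points <= 0 or not np.isfinite(self.max_points):
            raise ConfigurationError(f"{self.component}: max_points must be positive")
        if not (np.isfinite(self.zero_score) and np.isfinite(self.full_score)):
            raise ConfigurationError(f"{self.component}: thresholds must be finite")
        if self.special_rule == "none":
            if self.direction == "adequacy" and self.full_score <= self.zero_score:
                raise ConfigurationError(
                    f"{self.component}: adequacy requires full_score > zero_score"
                )
            if self.direction == "moderation" and self.full_score >= self.zero_score:
                raise ConfigurationError(
                    f"{self.component}: moderation requires full_score < zero_score"
                )
        elif self.special_rule == "alcohol_band":
            if None in (self.band_full_low, self.band_full_high, self.band_zero_high):
                raise ConfigurationError("alcohol_band standard missing band thresholds")
        else:
            raise ConfigurationError(f"unknown special_rule {self.special_rule!r}")


def _standards_from_frame(df: pd.DataFrame) -> list[ScoringStandard]:
    def _opt(v):
        return None if pd.isna(v) else float(v)

    out = []
    for _, row in df.iterrows():
        out.append(
            ScoringStandard(
                component=row["component"],
                index=row["index"],
                amount_column=row["amount_column"],
                direction=row["direction"],
                max_points=float(row["max_points"]),
                zero_score=float(row["zero_score"]),
                full_score=float(row["full_score"]),
                basis=row["basis"],
                denominator_column=(
                    None if pd.isna(row.get("denominator_column")) else row["denominator_column"]
                ),
                energy_per_unit=_opt(row.get("energy_per_unit")),
                special_rule=(
                    "none" if pd.isna(row.get("special_rule")) else row["special_rule"]
                ),
                band_full_low=_opt(row.get("band_full_low")),
                band_full_high=_opt(row.get("band_full_high")),
                band_zero_high=_opt(row.get("band_zero_high")),
                abstainer_points=_opt(row.get("abstainer_points")),
            )
        )
    return out


def load_standards(index: str) -> pd.DataFrame:
    """Return the packaged default scoring-standards table for ``index``."""
    try:
        fname = _STANDARD_FILES[index]
    except KeyError:
        raise ConfigurationError(f"unknown index {index!r}") from None
    with resources.files("dietprint.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)


def hei2015_standards() -> pd.DataFrame:
    return load_standards("hei2015")


def ahei2010_standards() -> pd.DataFrame:
    return load_standards("ahei2010")


def score_component(amount: float, standard: ScoringStandard) -> float:
    """Score one component given ``amount`` already expressed on its basis."""
    if amount < 0 or not np.isfinite(amount):
        raise ScoringError(f"{standard.component}: amount must be finite and >= 0")
    if standard.special_rule == "alcohol_band":
        return _score_alcohol_band(amount, standard)
    lo, hi, m = standard.zero_score, standard.full_score, standard.max_points
    if standard.direction == "adequacy":
        if amount >= hi:
            return m
        if amount <= lo:
            return 0.0
        return m * (amount - lo) / (hi - lo)
    # moderation: reverse scored
    if amount <= hi:
        return m
    if amount >= lo:
        return 0.0
    return m * (lo - amount) / (lo - hi)


def _score_alcohol_band(amount: float, std: ScoringStandard) -> float:
    """Two-sided trapezoid: full credit in the moderate band, declining to 0
    on either side; exact abstainers receive the partial credit recorded in
    the standards table."""
    m = std.max_points
    lo, hi, zhi = std.band_full_low, std.band_full_high, std.band_zero_high
    if amount == 0.0:
        return std.abstainer_points if std.abstainer_points is not None else 0.0
    if amount < lo:
        return m * amount / lo
    if amount <= hi:
        return m
    if amount < zhi:
        return m * (zhi - amount) / (zhi - hi)
    return 0.0


def amount_on_basis(
    record: Mapping[str, float],
    standard: ScoringStandard,
    *,
    energy: float,
    rescale_to: float | None = None,
) -> float:
    """Express a record's raw amount on the standard's scoring basis.

    ``rescale_to`` (e.g. 1849 kcal) applies the modified-AHEI energy
    adjustment to absolute per-day amounts.  Density and percent-energy bases
    are energy ratios and therefore unaffected by proportional rescaling.
    """
    amt = float(record[standard.amount_column])
    if amt < 0:
        raise ScoringError(f"{standard.component}: negative intake amount")
    if standard.basis == "per_1000_kcal":
        return amt / energy * DENSITY_BASIS_KCAL
    if standard.basis == "percent_energy":
        if standard.energy_per_unit is None:
            raise ConfigurationError(f"{standard.component}: percent_energy needs energy_per_unit")
        return amt * standard.energy_per_unit / energy * 100.0
    if standard.basis == "ratio":
        den = float(record[standard.denominator_column])
        if den <= 0:
            # degenerate ratio: any unsaturated intake with zero saturated fat
            # saturates the standard; nothing at all scores the floor
            return standard.full_score if amt > 0 else standard.zero_score
        return amt / den
    if standard.basis == "per_day":
        if rescale_to is not None:
            return amt * rescale_to / energy
        return amt
    raise ConfigurationError(f"{standard.component}: unknown basis {standard.basis!r}")


def _score_record(
    record: Mapping[str, float],
    standards: list[ScoringStandard],
    *,
    rescale_to: float | None,
    child_alcohol_rule: bool,
) -> dict[str, float]:
    energy = float(record["energy_kcal"])
    if energy <= 0:
        raise ScoringError("energy must be positive to score a record")
    comps: dict[str, float] = {}
    for std in standards:
        if (
            child_alcohol_rule
            and std.special_rule == "alcohol_band"
            and float(record.get("age", np.inf)) < 18
        ):
            raw = float(record[std.amount_column])
            comps[std.component] = std.max_points if raw == 0.0 else 0.0
            continue
        amt = amount_on_basis(record, std, energy=energy, rescale_to=rescale_to)
        comps[std.component] = score_component(amt, std)
    comps["total"] = float(sum(v for k, v in comps.items() if k != "total"))
    return comps


def hei2015_score(
    record: Mapping[str, float], standards: pd.DataFrame | None = None
) -> dict[str, float]:
    """Score one record on HEI-2015 (13 components, max 100).

    ``record`` must carry ``energy_kcal`` and the raw per-day amount columns
    named in the standards table; densities per 1000 kcal are derived here.
    """
    df = hei2015_standards() if standards is None else standards
    return _score_record(
        record, _standards_from_frame(df), rescale_to=None, child_alcohol_rule=False
    )


def ahei2010_score(
    record: Mapping[str, float],
    standards: pd.DataFrame | None = None,
    *,
    modified: bool = True,
) -> dict[str, float]:
    """Score one record on AHEI-2010 (10 components, trans fat excluded).

    With ``modified=True`` absolute amounts are energy adjusted to the
    1849 kcal/d reference and individuals younger than 18 receive 10 alcohol
    points for zero reported consumption and 0 points otherwise.  With
    ``modified=False`` amounts are scored raw and the adult alcohol band
    applies to everyone.
    """
    df = ahei2010_standards() if standards is None else standards
    return _score_record(
        record,
        _standards_from_frame(df),
        rescale_to=AHEI_REFERENCE_KCAL if modified else None,
        child_alcohol_rule=modified,
    )


def score_individuals(
    records: pd.DataFrame,
    index: str,
    standards: pd.DataFrame | None = None,
    *,
    modified: bool = True,
    energy_policy: str = "exclude",
) -> pd.DataFrame:
    """Score every record; returns per-component columns plus ``total``.

    Records with non-positive energy are excluded with a warning under the
    default policy (``energy_policy='exclude'``) or raise under ``'strict'``.
    """
    if energy_policy not in {"exclude", "strict"}:
        raise ConfigurationError(f"unknown energy_policy {energy_policy!r}")
    bad = records["energy_kcal"] <= 0
    if bad.any():
        if energy_policy == "strict":
            raise ScoringError(f"{int(bad.sum())} record(s) with non-positive energy")
        warnings.warn(f"excluding {int(bad.sum())} record(s) with non-positive energy")
        records = records.loc[~bad]
    rows = []
    for _, rec in records.iterrows():
        if index == "hei2015":
            comps = hei2015_score(rec, standards)
        else:
            comps = ahei2010_score(rec, standards, modified=modified)
        comps["person_id"] = rec["person_id"]
        rows.append(comps)
    out = pd.DataFrame(rows).set_index("person_id")
    return out


def population_ratio_mean(
    records: pd.DataFrame,
    weights: np.ndarray | pd.Series,
    index: str,
    standards: pd.DataFrame | None = None,
    *,
    modified: bool = True,
) -> dict[str, float]:
    """Population mean score by the population-ratio method.

    Each component's population amount is the ratio of the weighted total
    intake to the weighted total energy, scaled to the component's basis, and
    that single amount is scored; components are summed.  Doubling all
    weights leaves the result unchanged.
    """
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise EstimationError("all weights must be strictly positive")
    if standards is None:
        standards = load_standards(index)
    stds = _standards_from_frame(standards)
    energy = records["energy_kcal"].to_numpy(dtype=float)
    tot_energy = float(np.sum(w * energy))
    if tot_energy <= 0:
        raise EstimationError("zero weighted total energy")
    rescale = index == "ahei2010" and modified
    comps: dict[str, float] = {}
    for std in stds:
        amt = records[std.amount_column].to_numpy(dtype=float)
        tot_amt = float(np.sum(w * amt))
        if std.basis == "per_1000_kcal":
            pop_amt = tot_amt / tot_energy * DENSITY_BASIS_KCAL
        elif std.basis == "percent_energy":
            pop_amt = tot_amt * std.energy_per_unit / tot_energy * 100.0
        elif std.basis == "ratio":
            den = float(np.sum(w * records[std.denominator_column].to_numpy(dtype=float)))
            if den <= 0:
                pop_amt = std.full_score if tot_amt > 0 else std.zero_score
            else:
                pop_amt = tot_amt / den
        elif std.basis == "per_day":
            if rescale:
                pop_amt = tot_amt / tot_energy * AHEI_REFERENCE_KCAL
            else:
                pop_amt = tot_amt / float(np.sum(w))
        else:  # pragma: no cover - validated at load
            raise ConfigurationError(f"unknown basis {std.basis!r}")
        comps[std.component] = score_component(pop_amt, std)
    comps["total"] = float(sum(v for k, v in comps.items() if k != "total"))
    return comps


def weighted_quantile(
    values: Iterable[float], weights: Iterable[float], probs: Iterable[float]
) -> np.ndarray:
    """Left-continuous inverse of the weighted ECDF at each probability."""
    x = np.asarray(list(values), dtype=float)
    w = np.asarray(list(weights), dtype=float)
    if (w <= 0).any():
        raise EstimationError("weights must be strictly positive")
    order = np.argsort(x, kind="mergesort")
    x, w = x[order], w[order]
    cdf = np.cumsum(w) / np.sum(w)
    out = []
    for p in probs:
        idx = int(np.searchsorted(cdf, p, side="left"))
        out.append(x[min(idx, len(x) - 1)])
    return np.asarray(out)


def assign_quintiles(
    scores: pd.Series | np.ndarray,
    weights: pd.Series | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign quintiles 1 (lowest) .. 5 (highest) at weighted 20/40/60/80th
    percentile cutpoints; ties at a cutpoint fall to the lower quintile.

    Returns ``(quintiles, cutpoints)``.  With ``weights=None`` the split is
    unweighted (equal weights).
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 5:
        raise EstimationError("need at least 5 individuals to form quintiles")
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    if np.unique(s).size == 1:
        warnings.warn("all scores identical; assigning everyone to quintile 1")
        return np.ones(s.size, dtype=int), np.repeat(s[0], 4)
    cuts = weighted_quantile(s, w, [0.2, 0.4, 0.6, 0.8])
    quint = 1 + np.sum(s[:, None] > cuts[None, :], axis=1)
    return quint.astype(int), cuts
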