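"""End-to-end orchestration: simulate/load -> disaggregate -> score ->
waste accounting -> design-based estimates and trend tests -> foodprint.

A run is driven by a single :class:`RunConfig` (YAML-serializable).  Every
output CSV carries a header comment with the config hash and seed so that a
run is identifiable and reproducible; identical config + seed reproduces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import commodity_mapping, diet_quality, foodprint, survey_stats, synthetic_data
from .errors import ConfigurationError
from .waste_accounting import (
    CATEGORY_COLUMNS,
    LOSS_STREAMS,
    partition_intakes,
    per_capita_breakdown,
)

STAGES = ["simulate", "map", "score", "account", "trend", "footprint"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_paths`` (CSV tables on disk) or ``synthetic``
    (generation spec block) must be provided.
    """

    output_dir: str = "results/run"
    seed: int = 0
    synthetic: dict | None = None
    input_paths: dict | None = None
    indices: tuple[str, ...] = ("hei2015", "ahei2010")
    weighted_quintiles: bool = True
    unmapped_policy: str = "drop"
    loss_missing_policy: str = "zero"
    monte_carlo: dict = field(
        default_factory=lambda: {"n_reps": 200, "draw_fraction": 0.5}
    )

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_paths is None):
            raise ConfigurationError(
                "exactly one of 'synthetic' or 'input_paths' must be set"
            )

    def as_dict(self) -> dict:
        d = asdict(self)
        d["indices"] = list(self.indices)
        return d

    @property
    def hash(self) -> str:
        blob = yaml.safe_dump(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.pop("monte_carlo", None) if raw.get("monte_carlo") is None else None
        if "indices" in raw:
            raw["indices"] = tuple(raw["indices"])
        return cls(**raw)


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig, *, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.hash} seed={cfg.seed}\n")
        df.to_csv(fh, index=index)


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic is not None:
        block = dict(cfg.synthetic)
        design_kw = dict(block.get("design", {}))
        design_kw.setdefault("seed", cfg.seed)
        design = synthetic_data.SurveyDesignSpec(**design_kw)
        pop = synthetic_data.PopulationSpec(**block.get("population", {}))
        tables = synthetic_data.generate_parameter_tables(
            pop.n_foods,
            pop.n_commodities,
            seed=design.seed,
            unmapped_food_fraction=pop.unmapped_food_fraction,
        )
        records = synthetic_data.generate_population(design, pop, tables)
        return records, tables
    paths = cfg.input_paths
    records = pd.read_csv(paths["recall"], comment="#")
    tables = {
        "recipes": pd.read_csv(paths["recipes"], comment="#"),
        "loss_profiles": pd.read_csv(paths["loss_profiles"], comment="#"),
        "standards_hei2015": pd.read_csv(paths["standards_hei2015"], comment="#")
        if "standards_hei2015" in paths
        else diet_quality.hei2015_standards(),
        "standards_ahei2010": pd.read_csv(paths["standards_ahei2010"], comment="#")
        if "standards_ahei2010" in paths
        else diet_quality.ahei2010_standards(),
    }
    ag = foodprint.AgronomicParameters(
        commodity_table=pd.read_csv(paths["commodity_table"], comment="#"),
        feed_table=pd.read_csv(paths["feed_table"], comment="#"),
        crop_table=pd.read_csv(paths["crop_table"], comment="#"),
        rates=pd.read_csv(paths["application_rates"], comment="#"),
    )
    tables["agronomic"] = ag
    ct = ag.commodity_table
    tables["commodity_groups"] = ct.set_index("commodity_id")["food_group"]
    return records, tables


def run_pipeline(cfg: RunConfig, *, stages: list[str] | None = None) -> dict:
    """Execute the pipeline and return the run manifest.

    ``stages`` may truncate the run (a prefix of :data:`STAGES` in order);
    each stage consumes the in-memory products of the previous ones and
    writes its tables under ``cfg.output_dir``.
    """
    stages = STAGES if stages is None else stages
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stage(s) {sorted(unknown)}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.hash,
        "seed": cfg.seed,
        "stages": list(stages),
        "artifacts": {},
        "counts": {},
    }
    art = manifest["artifacts"]

    records, tables = _load_inputs(cfg)
    manifest["counts"]["individuals"] = int(len(records))
    if "simulate" in stages and cfg.synthetic is not None:
        _write_csv(records, out / "recall.csv", cfg)
        art["recall"] = str(out / "recall.csv")

    if not any(s in stages for s in STAGES[1:]):
        _finish(manifest, out, cfg)
        return manifest

    # --- commodity mapping -------------------------------------------------
    intakes, coverage = commodity_mapping.disaggregate(
        records, tables["recipes"], unmapped_policy=cfg.unmapped_policy
    )
    manifest["counts"]["commodity_intake_rows"] = int(len(intakes))
    if "map" in stages:
        _write_csv(intakes, out / "commodity_intakes.csv", cfg)
        art["commodity_intakes"] = str(out / "commodity_intakes.csv")
        with open(out / "coverage_report.json", "w") as fh:
            json.dump(coverage.as_dict(), fh, indent=2)
        art["coverage_report"] = str(out / "coverage_report.json")

    weights = records.set_index("person_id")["weight"]
    design_cols = records.set_index("person_id")[["stratum", "psu", "weight", "age", "sex"]]

    # --- diet-quality scoring ---------------------------------------------
    scores: dict[str, pd.DataFrame] = {}
    if any(s in stages for s in ("score", "account", "trend", "footprint")):
        for index in cfg.indices:
            std = tables[f"standards_{index}"]
            sc = diet_quality.score_individuals(records, index, std)
            q, cuts = diet_quality.assign_quintiles(
                sc["total"],
                weights.reindex(sc.index) if cfg.weighted_quintiles else None,
            )
            sc["quintile"] = q
            scores[index] = sc
            pop_score = diet_quality.population_ratio_mean(
                records.set_index("person_id").loc[sc.index].reset_index(),
                weights.reindex(sc.index).to_numpy(),
                index,
                std,
            )
            if "score" in stages:
                _write_csv(sc.reset_index(), out / f"scores_{index}.csv", cfg)
                art[f"scores_{index}"] = str(out / f"scores_{index}.csv")
                _write_csv(
                    pd.DataFrame([pop_score]),
                    out / f"population_score_{index}.csv",
                    cfg,
                )
                art[f"population_score_{index}"] = str(
                    out / f"population_score_{index}.csv"
                )

    if not any(s in stages for s in ("account", "trend", "footprint")):
        _finish(manifest, out, cfg)
        return manifest

    # --- waste accounting ---------------------------------------------------
    breakdown = partition_intakes(
        intakes, tables["loss_profiles"], missing_policy=cfg.loss_missing_policy
    )
    group_map = tables["commodity_groups"]
    overall = per_capita_breakdown(breakdown, weights, group_map)
    per_person = (
        breakdown.groupby("person_id")[CATEGORY_COLUMNS]
        .sum()
        .reindex(weights.index, fill_value=0.0)
    )
    if "account" in stages:
        _write_csv(overall.reset_index(), out / "per_capita_breakdown.csv", cfg)
        art["per_capita_breakdown"] = str(out / "per_capita_breakdown.csv")
        for index, sc in scores.items():
            rows = []
            for q in sorted(sc["quintile"].unique()):
                ids = sc.index[sc["quintile"] == q]
                sub = breakdown[breakdown["person_id"].isin(ids)]
                if sub.empty:
                    continue
                bq = per_capita_breakdown(sub, weights.loc[ids], group_map)
                bq = bq.reset_index().assign(quintile=q)
                rows.append(bq)
            _write_csv(
                pd.concat(rows, ignore_index=True),
                out / f"breakdown_by_{index}_quintile.csv",
                cfg,
            )
            art[f"breakdown_by_{index}_quintile"] = str(
                out / f"breakdown_by_{index}_quintile.csv"
            )

    # --- survey estimates and trend tests -----------------------------------
    if "trend" in stages:
        aligned = design_cols.join(per_person, how="inner")
        est_rows = []
        for cat in CATEGORY_COLUMNS:
            est = survey_stats.weighted_mean(
                aligned[cat], aligned["weight"], aligned["stratum"], aligned["psu"]
            )
            est_rows.append(
                {
                    "category": cat,
                    "mean_g": est.point,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "df": est.df,
                    "n": est.n,
                }
            )
        _write_csv(pd.DataFrame(est_rows), out / "design_estimates.csv", cfg)
        art["design_estimates"] = str(out / "design_estimates.csv")

        trend_rows = []
        for index, sc in scores.items():
            joined = aligned.join(sc["quintile"], how="inner")
            covs = pd.DataFrame(
                {
                    "age": joined["age"],
                    "male": (joined["sex"] == "male").astype(float),
                }
            )
            for adjusted in (False, True):
                tr = survey_stats.trend_test(
                    joined["total_demand"],
                    joined["quintile"],
                    joined["weight"],
                    joined["stratum"],
                    joined["psu"],
                    covariates=covs if adjusted else None,
                )
                trend_rows.append(
                    {
                        "index": index,
                        "outcome": "total_demand",
                        "adjusted": adjusted,
                        "slope_g_per_quintile": tr.slope,
                        "se": tr.se,
                        "p_value": tr.p_value,
                        "df": tr.df,
                    }
                )
        _write_csv(pd.DataFrame(trend_rows), out / "trend_tests.csv", cfg)
        art["trend_tests"] = str(out / "trend_tests.csv")

        if "ahei2010" in cfg.indices:
            std = tables["standards_ahei2010"]
            mod = diet_quality.score_individuals(records, "ahei2010", std, modified=True)
            orig = diet_quality.score_individuals(records, "ahei2010", std, modified=False)
            common = mod.index.intersection(orig.index)
            dc = design_cols.loc[common]
            wald = survey_stats.wald_difference_test(
                mod.loc[common, "total"],
                orig.loc[common, "total"],
                dc["weight"],
                dc["stratum"],
                dc["psu"],
            )
            _write_csv(pd.DataFrame([wald]), out / "ahei_modification_wald.csv", cfg)
            art["ahei_modification_wald"] = str(out / "ahei_modification_wald.csv")

    # --- foodprint ----------------------------------------------------------
    if "footprint" in stages:
        params = tables["agronomic"]
        population = float(weights.sum())
        wsum = population
        stream_fps: dict[str, foodprint.ResourceFootprint] = {}
        for stream in LOSS_STREAMS:
            per_cap = (
                breakdown.assign(
                    wmass=lambda d, s=stream: d[s]
                    * weights.reindex(d["person_id"]).to_numpy()
                )
                .groupby("commodity_id")["wmass"]
                .sum()
                / wsum
            )
            stream_fps[stream] = foodprint.footprint_from_demand(
                per_cap, params, population
            )
        total_fp = sum(
            list(stream_fps.values())[1:], start=list(stream_fps.values())[0]
        )
        shares = foodprint.attribute_to_loss_categories(stream_fps)
        by_cat = pd.concat(
            {name: fp.by_category for name, fp in stream_fps.items()}, names=["stream"]
        )
        _write_csv(by_cat.reset_index(), out / "footprint_by_stream.csv", cfg)
        art["footprint_by_stream"] = str(out / "footprint_by_stream.csv")
        _write_csv(
            total_fp.by_category.reset_index(), out / "footprint_total.csv", cfg
        )
        art["footprint_total"] = str(out / "footprint_total.csv")
        _write_csv(shares.reset_index(), out / "attribution_shares.csv", cfg)
        art["attribution_shares"] = str(out / "attribution_shares.csv")

        mc_cfg = cfg.monte_carlo or {}
        n = weights.size
        draw = max(2, int(round(mc_cfg.get("draw_fraction", 0.5) * n)))
        mc = foodprint.monte_carlo_footprint(
            breakdown.rename(columns={"total_demand": "stream_mass"})[
                ["person_id", "commodity_id", "stream_mass"]
            ].rename(columns={"stream_mass": "grams"}),
            weights,
            params,
            population,
            draw_size=draw,
            n_reps=int(mc_cfg.get("n_reps", 200)),
            seed=cfg.seed,
        )
        mc_tab = pd.DataFrame(
            {"mean": mc["mean"], "ci_low": mc["ci_low"], "ci_high": mc["ci_high"]}
        )
        _write_csv(mc_tab.reset_index(names="resource"), out / "footprint_mc.csv", cfg)
        art["footprint_mc"] = str(out / "footprint_mc.csv")

        # per-quintile footprints and resource trend tests
        fq_rows = []
        for index, sc in scores.items():
            for q in sorted(sc["quintile"].unique()):
                ids = sc.index[sc["quintile"] == q]
                w_q = weights.loc[ids]
                sub = breakdown[breakdown["person_id"].isin(ids)]
                per_cap = (
                    sub.assign(
                        wmass=lambda d: d["total_demand"]
                        * w_q.reindex(d["person_id"]).to_numpy()
                    )
                    .groupby("commodity_id")["wmass"]
                    .sum()
                    / float(w_q.sum())
                )
                fp = foodprint.footprint_from_demand(per_cap, params, population)
                fq_rows.append(
                    {"index": index, "quintile": int(q), **fp.totals.to_dict()}
                )
        _write_csv(
            pd.DataFrame(fq_rows), out / "footprint_by_quintile.csv", cfg
        )
        art["footprint_by_quintile"] = str(out / "footprint_by_quintile.csv")

    _finish(manifest, out, cfg)
    return manifest


def _finish(manifest: dict, out: Path, cfg: RunConfig) -> None:
    manifest["versions"] = {"dietprint": _version()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("dietprint")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"
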