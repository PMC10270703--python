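"""End-to-end orchestration: simulate → phenology → features → train → interpret.

A run is driven by a :class:`RunConfig` (constructed directly or loaded
from YAML) and a single global seed, fanned out to per-stage child seeds
by fixed offsets so each stage is independently reproducible. All outputs
are deterministic given the config: re-running writes byte-identical
files (no timestamps are embedded).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import features as feat
from . import gbdt, interpret, synthetic
from .phenology import PhenologyParams, derive_calendar
from .weather import DailyWeather, write_weather_csv

__all__ = ["RunConfig", "run_pipeline", "derive_calendars",
           "build_feature_table"]

# fixed seed offsets per stage
_SEED_DATASET = 0
_SEED_SPLIT = 1
_SEED_BOOT = 2


@dataclass
class RunConfig:
    """Configuration for one reproducible pipeline run."""

    out_dir: Path = Path("wheatgpc-run")
    # simulation
    n_counties: int = 40
    years: tuple[int, ...] = (2015, 2016, 2017, 2018)
    cultivars_per_county_year: int = 3
    # model hyperparameters
    n_trees: int = 100
    learning_rate: float = 0.1
    max_depth: int = 3
    min_leaf: int = 5
    train_fraction: float = 0.8
    tolerances: tuple[float, ...] = (0.3, 0.6)
    # interpretation
    pdp_top_k: int = 4
    pdp_max_grid: int = 10
    pdp2d_pairs: tuple[tuple[str, str], ...] = ()
    piecewise_features: tuple[str, ...] = ("lat",)
    n_boot: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        known = set(feat.FEATURE_COLUMNS)
        for name in list(self.piecewise_features) + [
                f for pair in self.pdp2d_pairs for f in pair]:
            if name not in known:
                raise ValueError(f"unknown feature in config: {name!r}")
        if not self.years:
            raise ValueError("years must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                if f.name == "pdp2d_pairs":
                    v = tuple(tuple(p) for p in v)
                elif isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        d["pdp2d_pairs"] = [list(p) for p in self.pdp2d_pairs]
        return d


def derive_calendars(weather: dict[str, dict[int, DailyWeather]],
                     params: PhenologyParams = PhenologyParams()
                     ) -> pd.DataFrame:
    """Derive a stage calendar for every county-season; one row each."""
    rows = []
    for county, seasons in weather.items():
        for year, series in seasons.items():
            cal = derive_calendar(series, params)
            rows.append({
                "county_id": county, "year": year,
                "sowing": cal.sowing, "dormancy_onset": cal.dormancy_onset,
                "regreening": cal.regreening, "jointing": cal.jointing,
                "flowering": cal.flowering, "filling": cal.filling,
                "maturity": cal.maturity,
                "warnings": "; ".join(cal.warnings),
            })
    return pd.DataFrame(rows)


def build_feature_table(weather: dict[str, dict[int, DailyWeather]],
                        sites: pd.DataFrame, gpc: pd.DataFrame | None,
                        params: PhenologyParams = PhenologyParams()
                        ) -> pd.DataFrame:
    """Phenology + aggregation for every county-season, merged with GPC."""
    site_ix = sites.set_index("county_id")
    records = []
    for county, seasons in weather.items():
        site = {"latitude": site_ix.loc[county, "latitude"],
                "longitude": site_ix.loc[county, "longitude"]}
        for year, series in seasons.items():
            cal = derive_calendar(series, params)
            rec = feat.build_features(series, cal, site)
            rec["year"] = year
            records.append(rec)
    return feat.feature_table(records, gpc)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write a machine-readable report.

    Outputs under ``config.out_dir``: the simulated tables, the stage
    calendars, the 29-column feature table (with a JSON sidecar mapping
    names to window and statistic), the serialized model, evaluation
    metrics, the normalized importance table, centered PDP profiles for
    the top-k features, any requested 2-D PDP surfaces, broken-stick fits,
    and ``report.json`` summarizing everything.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # 1. simulate
    sites, weather, gpc = synthetic.generate_dataset(
        config.n_counties, list(config.years),
        config.cultivars_per_county_year, seed=config.seed + _SEED_DATASET)
    sites.to_csv(out / "sites.csv", index=False)
    gpc.to_csv(out / "gpc.csv", index=False)
    write_weather_csv([s for by_year in weather.values()
                       for s in by_year.values()], out / "weather.csv")

    # 2-3. phenology + features
    calendars = derive_calendars(weather)
    calendars.to_csv(out / "calendars.csv", index=False)
    table = build_feature_table(weather, sites, gpc)
    table.to_csv(out / "features.csv", index=False)
    (out / "features_schema.json").write_text(
        json.dumps(feat.FEATURE_SPEC, indent=1))

    # 4. train + evaluate
    train, test = gbdt.split_train_test(table, config.train_fraction,
                                        seed=config.seed + _SEED_SPLIT)
    model = gbdt.fit_gbdt(train[feat.FEATURE_COLUMNS], train["gpc_pct"],
                          n_trees=config.n_trees,
                          learning_rate=config.learning_rate,
                          max_depth=config.max_depth,
                          min_leaf=config.min_leaf)
    gbdt.save_model(model, out / "model.json")
    metrics = gbdt.evaluate(model, test[feat.FEATURE_COLUMNS],
                            test["gpc_pct"], config.tolerances)
    (out / "metrics.json").write_text(json.dumps(metrics.to_dict(), indent=1))
    importance = gbdt.feature_importance(model).sort_values(ascending=False)
    importance.rename_axis("feature").to_csv(out / "importance.csv")

    # 5. interpret
    ref = table[feat.FEATURE_COLUMNS]
    top = list(importance.index[:config.pdp_top_k])
    pdp_summaries = {}
    for name in top:
        res = interpret.pdp_1d(model, ref, name, config.pdp_max_grid)
        res.to_frame().to_csv(out / f"pdp_{name}.csv", index=False)
        pdp_summaries[name] = {
            "grid_min": float(res.grid[0]), "grid_max": float(res.grid[-1]),
            "n_grid": res.n_grid,
            "pd_range": float(res.centered_pd.max() - res.centered_pd.min()),
        }
    for a, b in config.pdp2d_pairs:
        res2 = interpret.pdp_2d(model, ref, a, b, config.pdp_max_grid)
        res2.to_frame().to_csv(out / f"pdp2d_{a}__{b}.csv", index=False)
    piecewise = {}
    for name in config.piecewise_features:
        fit = interpret.piecewise_fit(
            table[name], table["gpc_pct"], n_boot=config.n_boot,
            seed=config.seed + _SEED_BOOT)
        piecewise[name] = fit.to_dict()
    (out / "piecewise.json").write_text(json.dumps(piecewise, indent=1))

    report = {
        "config": config.to_dict(),
        "rows": {"sites": len(sites), "gpc": len(gpc),
                 "county_years": len(table),
                 "train": len(train), "test": len(test)},
        "n_predictors": len(feat.FEATURE_COLUMNS),
        "metrics": metrics.to_dict(),
        "importance_top10": {k: float(v)
                             for k, v in importance.head(10).items()},
        "pdp": pdp_summaries,
        "piecewise": piecewise,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
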