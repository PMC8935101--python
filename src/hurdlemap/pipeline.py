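"""End-to-end orchestration: simulate → code covariates → fit → map.

A run is fully reproducible from (config, seed): all randomness flows from the
single configured seed through ``numpy.random.SeedSequence`` spawning, and
every artefact (data files, posterior store, odds-ratio tables, risk-surface
layers, JSON manifest) is a deterministic function of them. Unknown
configuration keys are rejected outright.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point

from . import covariates as cov
from .inference import Posterior, PriorConfig, SamplerConfig, diagnostics, fit, summarize
from .io import read_geojson, write_geojson
from .matern import MaternParams, kappa_from_range
from .model import PanelDataset
from .risk import build_risk_surface, export_layers
from .synthetic import SyntheticScenario, TractFrame, default_scenario, simulate_scenario

log = logging.getLogger("hurdlemap")

MODES = ("simulate", "fit", "map", "full")


@dataclass(frozen=True)
class MapConfig:
    hi_cutoff: float = 0.8
    lo_cutoff: float = 0.2
    part: str = "binomial"
    level: float = 0.95


@dataclass(frozen=True)
class RunConfig:
    mode: str = "full"
    seed: int = 0
    out_dir: str = "runs/out"
    scenario: SyntheticScenario = field(default_factory=default_scenario)
    prior: PriorConfig = field(default_factory=PriorConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    map: MapConfig = field(default_factory=MapConfig)
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def _check_keys(block: dict, allowed, where: str) -> None:
    unknown = set(block) - set(allowed)
    if unknown:
        raise ValueError(f"unknown configuration key(s) in {where}: {sorted(unknown)}")


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Parse a YAML run configuration with fail-fast schema validation."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    _check_keys(raw, ("mode", "seed", "out_dir", "scenario", "prior", "sampler", "map", "inputs"), "run config")
    kwargs = {k: raw[k] for k in ("mode", "seed", "out_dir", "inputs") if k in raw}
    if "scenario" in raw:
        kwargs["scenario"] = _scenario_from_dict(raw["scenario"])
    if "prior" in raw:
        _check_keys(raw["prior"], PriorConfig.__dataclass_fields__, "prior")
        kwargs["prior"] = PriorConfig(**raw["prior"])
    if "sampler" in raw:
        _check_keys(raw["sampler"], SamplerConfig.__dataclass_fields__, "sampler")
        samp = dict(raw["sampler"])
        if "latent_components" in samp:
            samp["latent_components"] = tuple(samp["latent_components"])
        kwargs["sampler"] = SamplerConfig(**samp)
    if "map" in raw:
        _check_keys(raw["map"], MapConfig.__dataclass_fields__, "map")
        kwargs["map"] = MapConfig(**raw["map"])
    return RunConfig(**kwargs)


def _scenario_from_dict(block: dict) -> SyntheticScenario:
    _check_keys(
        block,
        tuple(SyntheticScenario.__dataclass_fields__) + ("matern",),
        "scenario",
    )
    kwargs = dict(block)
    if "matern" in kwargs:
        m = dict(kwargs.pop("matern"))
        _check_keys(m, ("sigma2", "nu", "kappa", "range"), "scenario.matern")
        nu = float(m.get("nu", 1.0))
        if "range" in m:
            kappa = kappa_from_range(nu, float(m.pop("range")))
        else:
            kappa = float(m["kappa"])
        kwargs["matern"] = MaternParams(sigma2=float(m["sigma2"]), nu=nu, kappa=kappa)
    defaults = default_scenario()
    kwargs.setdefault("true_betas_binomial", defaults.true_betas_binomial)
    kwargs.setdefault("true_betas_poisson", defaults.true_betas_poisson)
    return SyntheticScenario(**kwargs)


def config_digest(config: RunConfig) -> str:
    """Hash of the run-defining configuration (output location excluded)."""
    plain = _as_plain(config)
    plain.pop("out_dir", None)
    blob = json.dumps(plain, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _as_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# data I/O


def write_dataset(tracts: TractFrame, panel: PanelDataset, out_dir) -> dict:
    """Write geometry GeoJSON, tract-covariate CSV, and the panel CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "geometry": out / "geometry.geojson",
        "covariates": out / "covariates.csv",
        "panel": out / "panel.csv",
    }
    write_geojson(tracts.table[["x", "y", "population"]], tracts.geometry, paths["geometry"])
    tracts.table.to_csv(paths["covariates"])
    panel.obs.to_csv(paths["panel"], index=False)
    return paths


def read_panel(panel_csv, covariates_csv, geometry_path) -> tuple[TractFrame, PanelDataset]:
    """Assemble a validated PanelDataset from on-disk files.

    The panel CSV either holds pre-aggregated counts (columns ``tract_id``,
    ``period``, ``count``) or point observations (columns ``x``, ``y``,
    ``period``), which are assigned to the containing tract polygon and
    counted. A point on a shared boundary goes to the tract whose id is
    smallest in string (lexicographic) order; a point outside every polygon is
    an error reporting its coordinates.
    """
    geo_table, geoms = read_geojson(geometry_path)
    covs = pd.read_csv(covariates_csv).set_index("tract_id")
    orphans = set(covs.index).symmetric_difference(set(geo_table.index))
    if orphans:
        raise ValueError(
            f"tract_id mismatch between covariates and geometry; orphan ids: {sorted(orphans)[:10]}"
        )
    covs = covs.loc[geo_table.index]
    if "x" not in covs.columns:
        covs["x"] = geo_table["x"] if "x" in geo_table.columns else [g.centroid.x for g in geoms]
    if "y" not in covs.columns:
        covs["y"] = geo_table["y"] if "y" in geo_table.columns else [g.centroid.y for g in geoms]
    tracts = TractFrame(covs, geoms)

    raw = pd.read_csv(panel_csv)
    if {"tract_id", "period", "count"}.issubset(raw.columns):
        obs = raw[["tract_id", "period", "count"]].copy()
    elif {"x", "y", "period"}.issubset(raw.columns):
        obs = _aggregate_points(raw, tracts)
    else:
        raise ValueError(
            "panel CSV must have columns (tract_id, period, count) or (x, y, period)"
        )
    unknown = set(obs["tract_id"]) - set(covs.index)
    if unknown:
        raise ValueError(f"panel references unknown tract ids: {sorted(unknown)[:10]}")

    design = cov.build_design_matrix(tracts.table)
    panel = PanelDataset(
        obs=obs.reset_index(drop=True),
        n_trials=tracts.table["population"],
        design=design,
        centroids=tracts.centroids,
    )
    return tracts, panel


def _aggregate_points(raw: pd.DataFrame, tracts: TractFrame) -> pd.DataFrame:
    ids = list(tracts.table.index)
    rows = []
    for _, rec in raw.iterrows():
        pt = Point(float(rec["x"]), float(rec["y"]))
        hits = [tid for tid, geom in zip(ids, tracts.geometry) if geom.covers(pt)]
        if not hits:
            raise ValueError(f"observation at ({pt.x}, {pt.y}) lies outside every tract polygon")
        rows.append({"tract_id": min(hits, key=str), "period": int(rec["period"])})
    pts = pd.DataFrame(rows)
    obs = (
        pts.groupby(["tract_id", "period"]).size().rename("count").reset_index()
    )
    # explicit zeros for observed periods without points, per tract
    full = pd.MultiIndex.from_product(
        [ids, sorted(pts["period"].unique())], names=["tract_id", "period"]
    )
    obs = (
        obs.set_index(["tract_id", "period"]).reindex(full, fill_value=0).reset_index()
    )
    return obs


# ---------------------------------------------------------------------------
# stages


def run_simulate(config: RunConfig) -> dict:
    scenario = config.scenario
    if config.seed is not None:
        from dataclasses import replace

        scenario = replace(scenario, seed=config.seed)
    log.info("simulating scenario: %d tracts x %d periods", scenario.n_tracts, scenario.n_periods)
    tracts, effects, panel = simulate_scenario(scenario)
    paths = write_dataset(tracts, panel, Path(config.out_dir) / "data")
    return {"tracts": tracts, "effects": effects, "panel": panel, "paths": paths}


def run_fit(config: RunConfig, panel: PanelDataset) -> dict:
    out = Path(config.out_dir)
    log.info(
        "fitting: %d observations, %d chains x %d draws",
        len(panel.obs), config.sampler.chains, config.sampler.draws,
    )
    posterior = fit(panel, config.prior, config.sampler, seed=config.seed)
    posterior.save(out / "posterior")
    tables = {}
    for part in ("binomial", "poisson"):
        for level in (0.90, 0.95):
            tab = summarize(posterior, level=level, part=part)
            name = f"or_{part}_{int(level * 100)}"
            tab.to_csv(out / f"{name}.csv")
            tables[name] = tab
    if config.sampler.chains >= 2 and config.sampler.draws >= 100:
        diagnostics(posterior).to_csv(out / "diagnostics.csv")
    log.info("posterior and odds-ratio tables written to %s", out)
    return {"posterior": posterior, "tables": tables}


def run_map(config: RunConfig, posterior: Posterior, tracts: TractFrame) -> dict:
    surface = build_risk_surface(
        posterior,
        tract_ids=list(tracts.table.index),
        level=config.map.level,
        hi_cutoff=config.map.hi_cutoff,
        lo_cutoff=config.map.lo_cutoff,
        part=config.map.part,
    )
    paths = export_layers(tracts, surface, Path(config.out_dir) / "layers")
    log.info("risk-surface layers written to %s", paths["geojson"].parent)
    return {"surface": surface, "paths": paths}


def run_full(config: RunConfig) -> dict:
    """simulate → design → fit → summarise → map, with a JSON run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        sim = run_simulate(config)
        stage = "fit"
        fitres = run_fit(config, sim["panel"])
        stage = "map"
        mapres = run_map(config, fitres["posterior"], sim["tracts"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    import hurdlemap

    def rel(p) -> str:
        return str(Path(p).resolve().relative_to(out.resolve()))

    plain_config = _as_plain(config)
    plain_config.pop("out_dir", None)  # manifest paths are relative: relocatable
    manifest = {
        "config": plain_config,
        "config_digest": config_digest(config),
        "seed": config.seed,
        "version": hurdlemap.__version__,
        "artefacts": {
            "data": {k: rel(v) for k, v in sim["paths"].items()},
            "posterior": "posterior",
            "or_tables": [f"or_{p}_{l}.csv" for p in ("binomial", "poisson") for l in (90, 95)],
            "layers": {k: rel(v) for k, v in mapres["paths"].items()},
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete; manifest at %s", out / "manifest.json")
    return {**sim, **fitres, **mapres, "manifest": manifest}
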