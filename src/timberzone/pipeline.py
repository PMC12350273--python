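"""Configuration-driven end-to-end orchestration.

One :class:`RunConfig` (YAML-serialisable) drives the whole synthetic study:
simulate landscape -> sample presences -> thin -> pseudo-absences -> VIF
screen -> fit RF + MaxEnt -> evaluate -> predict per period/scenario ->
trait links with lag analysis -> zoning -> area/change accounting.  A single
global seed expands deterministically into per-stage seeds, and the run
manifest records config, seeds and SHA-256 digests of every output file so
a rerun reproduces byte-identical tables and lattices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids import write_climate_grid, write_surface
from .occurrences import assemble_dataset, generate_pseudo_absences, thin_occurrences
from .screening import iterative_vif_screen
from .sdm import MaxEntSDM, RandomForestSDM
from .synthetic import (
    SCENARIO_PRESETS,
    TruthParams,
    annual_suitability_series,
    generate_climate_grid,
    project_future_climate,
    rings_to_chronological,
    sample_occurrences,
    simulate_traits,
    true_suitability_surface,
)
from .traits import fit_trait_model, lag_analysis
from .zoning import (
    ZoningConfig,
    area_summary,
    change_stats,
    classify_habitat,
    delineate_timber_zones,
    predict_trait_surface,
    rank_percentile_zones,
)

log = logging.getLogger("timberzone")

STAGES = ("simulate", "thin", "pseudo_absences", "screen", "fit", "evaluate",
          "predict", "link", "zone", "summarize")


@dataclass
class RunConfig:
    """Everything needed to reproduce one study run."""

    seed: int = 0
    grid_shape: tuple[int, int] = (60, 80)
    smoothness: float = 4.0
    cell_size_km: float = 10.0
    n_presence: int = 213
    n_pseudo_absence: int = 587
    thin_km: float = 5.0
    vif_threshold: float = 10.0
    rf_trees: int = 500
    rf_train_fraction: float = 0.75
    maxent_regularization: float = 1.0
    maxent_cv_folds: int = 10
    maxent_hinge_knots: int = 10
    n_trait_sites: int = 27
    n_rings: int = 20
    lags: tuple[int, ...] = (0, 1)
    scenarios: tuple[tuple[str, str], ...] = (
        ("2020s", "SSP2-4.5"), ("2020s", "SSP5-8.5"),
        ("2050s", "SSP2-4.5"), ("2050s", "SSP5-8.5"))
    zoning: ZoningConfig | None = field(default_factory=ZoningConfig)
    truth: TruthParams = field(default_factory=TruthParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zoning"] = dataclasses.asdict(self.zoning) if self.zoning else None
        d["truth"] = dataclasses.asdict(self.truth)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("zoning") is not None:
            z = dict(d["zoning"])
            z["habitat_breaks"] = tuple(z.get("habitat_breaks", (0.2, 0.4, 0.6)))
            d["zoning"] = ZoningConfig(**z)
        if "truth" in d and isinstance(d["truth"], dict):
            t = dict(d["truth"])
            for key in ("growth_coeffs", "density_coeffs"):
                if key in t:
                    t[key] = tuple(t[key])
            d["truth"] = TruthParams(**t)
        for key in ("grid_shape", "lags"):
            if key in d:
                d[key] = tuple(d[key])
        if "scenarios" in d:
            d["scenarios"] = tuple(tuple(s) for s in d["scenarios"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def expand_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2^31) from one global seed."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {stage: int(s & 0x7FFFFFFF) for stage, s in zip(STAGES, state)}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    """In-memory handles plus the serialised manifest."""

    manifest: dict
    config: RunConfig
    grid: object = None
    truth_surface: object = None
    dataset: pd.DataFrame | None = None
    retained: list | None = None
    rf: object = None
    maxent: object = None
    selected_model: str = ""
    surfaces: dict | None = None
    traits: pd.DataFrame | None = None
    links: dict | None = None
    lag_result: object = None
    summaries: dict | None = None
    changes: dict | None = None


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    """Execute all stages in dependency order and write the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = expand_seeds(config.seed)
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds,
                      "config": config.to_dict(), "stages": [], "files": {}}
    result = PipelineResult(manifest=manifest, config=config)

    def done(stage: str, *files: Path):
        for f in files:
            manifest["files"][str(f.relative_to(out))] = _digest(f)
        manifest["stages"].append(stage)
        log.info("stage complete: %s", stage)

    # -- simulate -----------------------------------------------------------
    grid = generate_climate_grid(
        config.grid_shape, seeds["simulate"], smoothness=config.smoothness,
        cell_size_km=config.cell_size_km)
    truth_surface = true_suitability_surface(grid, config.truth)
    presences = sample_occurrences(truth_surface, config.n_presence,
                                   seeds["simulate"])
    grid_dir = write_climate_grid(grid, out / "climate_current")
    pres_path = out / "presences.csv"
    presences.to_csv(pres_path, index=False)
    result.grid, result.truth_surface = grid, truth_surface
    done("simulate", pres_path, *sorted(grid_dir.glob("*")))

    # -- thin ---------------------------------------------------------------
    thinned = thin_occurrences(presences, min_km=config.thin_km,
                               seed=seeds["thin"])
    thin_path = out / "presences_thinned.csv"
    thinned.to_csv(thin_path, index=False)
    done("thin", thin_path)

    # -- pseudo-absences ----------------------------------------------------
    absences = generate_pseudo_absences(
        config.n_pseudo_absence, grid.valid, grid.transform, thinned,
        seeds["pseudo_absences"])
    dataset = assemble_dataset(thinned, absences)
    ds_path = out / "dataset.csv"
    dataset.to_csv(ds_path, index=False)
    result.dataset = dataset
    done("pseudo_absences", ds_path)

    # -- screen (presence-site climate values only) -------------------------
    r, c = grid.transform.cell_index(thinned["lon"].to_numpy(),
                                     thinned["lat"].to_numpy())
    presence_table = grid.table(r, c)
    retained, removal_log = iterative_vif_screen(
        presence_table, threshold=config.vif_threshold)
    screen_path = out / "screen.json"
    screen_path.write_text(json.dumps(
        {"retained": retained,
         "removed": [{"variable": v, "vif": vif if np.isfinite(vif) else "inf"}
                     for v, vif in removal_log]}, indent=2))
    result.retained = retained
    done("screen", screen_path)

    # -- fit ----------------------------------------------------------------
    rd, cd = grid.transform.cell_index(dataset["lon"].to_numpy(),
                                       dataset["lat"].to_numpy())
    features = grid.table(rd, cd)[retained]
    labels = dataset["label"].to_numpy()
    rf = RandomForestSDM(features, labels, n_trees=config.rf_trees,
                         train_fraction=config.rf_train_fraction,
                         seed=seeds["fit"]).fit()
    maxent = MaxEntSDM(
        features[labels == 1], features[labels == 0],
        regularization_multiplier=config.maxent_regularization,
        n_hinge_knots=config.maxent_hinge_knots,
        cv_folds=config.maxent_cv_folds, seed=seeds["fit"]).fit()
    result.rf, result.maxent = rf, maxent
    fit_path = out / "models.json"
    fit_path.write_text(json.dumps({
        "rf": {"n_trees": config.rf_trees, "oob_error": rf.oob_error,
               "importance": rf.importance["importance"].to_dict()},
        "maxent": {"intercept": maxent.intercept,
                   "coefficients": {k: v for k, v in maxent.coefs.items() if v != 0},
                   "contribution_pct": maxent.contribution.to_dict()},
    }, indent=2))
    done("fit", fit_path)

    # -- evaluate -----------------------------------------------------------
    eval_path = out / "evaluation.json"
    eval_path.write_text(json.dumps({
        "rf": {"oob_error": rf.oob_error, "accuracy_pct": rf.accuracy_pct,
               "holdout_auc": rf.holdout.auc, "holdout_tss": rf.holdout.tss},
        "maxent": {"train_auc": maxent.train_auc,
                   "cv_auc_mean": maxent.cv_summary["auc"][0],
                   "cv_auc_sd": maxent.cv_summary["auc"][1],
                   "cv_omission_mean": maxent.cv_summary["omission_rate"][0]},
    }, indent=2))
    done("evaluate", eval_path)

    # -- predict per period/scenario (both models) --------------------------
    grids = {("1961-1990", "current"): grid}
    for key in config.scenarios:
        grids[tuple(key)] = project_future_climate(grid,
                                                   SCENARIO_PRESETS[tuple(key)])
    all_surfaces = {
        "RF": {k: rf.predict_surface(gr) for k, gr in grids.items()},
        "MaxEnt": {k: maxent.predict_surface(gr) for k, gr in grids.items()},
    }
    files = []
    for tag, surfs in all_surfaces.items():
        for (period, scen), surf in surfs.items():
            p = out / f"suitability_{tag}_{period}_{scen.replace('.', '')}.asc"
            files.append(write_surface(surf, p))
    done("predict", *files)

    # -- link (traits; per model, then select the better-aligned model) -----
    rng = np.random.default_rng(seeds["link"])
    site_idx = rng.choice(len(thinned), size=min(config.n_trait_sites,
                                                 len(thinned)), replace=False)
    sites = thinned.iloc[np.sort(site_idx)].reset_index(drop=True)
    n_years = config.n_rings + 1
    truth_series = annual_suitability_series(
        grid, lambda g: true_suitability_surface(g, config.truth, reference=grid),
        sites, n_years, seeds["link"])
    traits = simulate_traits(sites, truth_series, config.truth,
                             n_rings=config.n_rings, seed=seeds["link"])
    traits_path = out / "traits.csv"
    traits.to_csv(traits_path, index=False)

    rs, cs = grid.transform.cell_index(sites["lon"].to_numpy(),
                                       sites["lat"].to_numpy())
    links: dict = {}
    for tag in ("RF", "MaxEnt"):
        site_suit = all_surfaces[tag][("1961-1990", "current")].values[rs, cs]
        links[tag] = {
            "site_suitability": site_suit,
            "growth20": fit_trait_model(site_suit, traits["growth20_cm"],
                                        trait_name="20-year DBH growth (cm)"),
            "density": fit_trait_model(site_suit, traits["density_gcm3"],
                                       trait_name="wood basic density (g/cm3)"),
        }
    # the model whose suitability aligns better with field traits carries
    # the projections (growth R^2 as the criterion)
    selected = max(("RF", "MaxEnt"),
                   key=lambda t: links[t]["growth20"].r_squared)
    sel_model = rf if selected == "RF" else maxent
    surfaces = all_surfaces[selected]
    model_series = annual_suitability_series(
        grid, sel_model.predict_surface, sites, n_years, seeds["link"])
    growth_chron = rings_to_chronological(traits, config.n_rings)
    lag_result = lag_analysis(growth_chron, model_series, lags=config.lags)
    link_path = out / "link.json"
    link_path.write_text(json.dumps({
        "selected_model": selected,
        **{tag: {
            "growth20": {"form": links[tag]["growth20"].form,
                         "r_squared": links[tag]["growth20"].r_squared,
                         "coefs": links[tag]["growth20"].coefs},
            "density": {"form": links[tag]["density"].form,
                        "r_squared": links[tag]["density"].r_squared,
                        "coefs": links[tag]["density"].coefs},
        } for tag in links},
        "lag_r2": {str(k): v for k, v in lag_result.r2_by_lag.items()},
        "lag_winner": lag_result.winner,
    }, indent=2))
    result.surfaces = surfaces
    result.selected_model = selected
    result.traits, result.links, result.lag_result = traits, links, lag_result
    done("link", traits_path, link_path)

    # -- zone + summarize (optional) ----------------------------------------
    if config.zoning is None:
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        return result

    cfg = config.zoning
    lag_link = lag_result.results[1] if 1 in lag_result.results \
        else lag_result.results[min(lag_result.results)]
    density_link = fit_trait_model(
        links[selected]["site_suitability"], traits["density_gcm3"],
        forms=("linear",), trait_name="wood basic density (g/cm3)")
    summaries: dict = {}
    zone_files = []
    for key, surf in surfaces.items():
        habitat = classify_habitat(surf, cfg)
        growth_lat, _ = predict_trait_surface(lag_link, surf)
        density_lat, _ = predict_trait_surface(density_link, surf)
        eligible = delineate_timber_zones(growth_lat, density_lat, surf, cfg)
        ranked = rank_percentile_zones(growth_lat, density_lat, eligible, cfg)
        summaries[key] = {
            "habitat": area_summary(habitat),
            "timber": area_summary(ranked),
        }
    done("zone", *zone_files)

    current = summaries[("1961-1990", "current")]
    changes = {}
    for key in config.scenarios:
        changes[tuple(key)] = {
            "habitat": change_stats(current["habitat"],
                                    summaries[tuple(key)]["habitat"]),
            "timber": change_stats(current["timber"],
                                   summaries[tuple(key)]["timber"]),
        }
    summary_path = out / "area_summaries.json"
    summary_path.write_text(json.dumps({
        "areas": {f"{p}|{s}": {
            "habitat": summaries[(p, s)]["habitat"].area_km2,
            "habitat_share_pct": summaries[(p, s)]["habitat"].share_pct,
            "timber": summaries[(p, s)]["timber"].area_km2,
        } for (p, s) in summaries},
        "change_vs_current_pct": {
            f"{p}|{s}": changes[(p, s)] for (p, s) in changes},
    }, indent=2))
    result.summaries, result.changes = summaries, changes
    done("summarize", summary_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return result
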