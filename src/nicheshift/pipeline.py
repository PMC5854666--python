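"""End-to-end orchestration: config, staged execution, run report.

The pipeline is a chain of stages, each reading its inputs from and writing
its outputs to plain-text files in a run directory, so any stage can be
re-run in isolation from persisted intermediates:

    simulate    -> climate.csv, soil.csv, occurrences.csv, species.json,
                   protected_areas.geojson, regions.csv
    predictors  -> predictor_report.csv
    model       -> suitability.csv, model_report.csv
    overlay     -> overlay_index.csv, protected_land.csv
    metrics     -> pa_impacts.csv, protection_change.csv,
                   land_distributions.csv, summary.json

One master seed determines all random streams (independent substreams per
stage and per species), so a re-run with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enm, metrics, overlay, predictors, synthetic
from .grid import LandscapeGrid, make_grid
from .synthetic import FUTURE, REFERENCE

log = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    seed: int = 0
    # synthetic landscape
    n_rows: int = 30
    n_cols: int = 20
    cell_size: float = 20.0
    warming: float = 3.0
    n_per_taxon: dict = field(default_factory=lambda: dict(
        synthetic.DEFAULT_N_PER_TAXON))
    sampling_rate: float = 1.0
    pa_count: int = 150
    pa_median_area: float = 5.0
    pa_sigma_log: float = 1.2
    pa_size_cap: float = 50.0
    n_provinces: int = 3
    n_regions_per_province: int = 3
    hierarchy_method: str = "bands"
    # predictor screening
    correlation_threshold: float = 0.6
    predictor_priority: list = field(default_factory=lambda: list(
        synthetic.DEFAULT_PRIORITY))
    max_vars: dict = field(default_factory=lambda: dict(
        predictors.DEFAULT_MAX_VARS))
    # ensemble niche models
    families: tuple = enm.DEFAULT_FAMILIES
    n_repetitions: int = enm.DEFAULT_N_REPETITIONS
    buffer_cells: float = enm.DEFAULT_BUFFER_CELLS
    auc_floor: float = enm.DEFAULT_AUC_FLOOR
    calibration_fraction: float = enm.DEFAULT_CALIBRATION_FRACTION
    min_presences: int = 10
    # metric reporting
    class_edges: tuple = tuple(float(e) for e in range(0, 101, 10))
    schema_version: int = CONFIG_SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(self.families)
        d["class_edges"] = list(self.class_edges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "families" in d:
            d["families"] = tuple(d["families"])
        if "class_edges" in d:
            d["class_edges"] = tuple(float(e) for e in d["class_edges"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def grid(self) -> LandscapeGrid:
        return make_grid(self.n_rows, self.n_cols, self.cell_size)


def validate_config(config: RunConfig) -> list[str]:
    """Schema and cross-field checks; violations are the return value."""
    v: list[str] = []
    if config.n_rows < 1 or config.n_cols < 1:
        v.append("grid dimensions (n_rows, n_cols) must be >= 1")
    if config.cell_size <= 0:
        v.append("cell_size must be > 0")
    if sum(config.n_per_taxon.values()) <= 0:
        v.append("n_per_taxon: at least one species is required")
    if any(n < 0 for n in config.n_per_taxon.values()):
        v.append("n_per_taxon: counts must be >= 0")
    if not 0.0 <= config.sampling_rate <= 1.0:
        v.append("sampling_rate must be in [0, 1]")
    if config.pa_count < 1:
        v.append("pa_count must be >= 1")
    if config.pa_size_cap > (config.n_rows * config.n_cols
                             * config.cell_size ** 2):
        v.append("pa_size_cap exceeds the grid extent area")
    if config.hierarchy_method == "bands" and \
            config.n_provinces > config.n_rows:
        v.append("n_provinces exceeds n_rows in band mode")
    if not 0.0 < config.correlation_threshold <= 1.0:
        v.append("correlation_threshold must be in (0, 1]")
    if not 0.5 <= config.auc_floor <= 1.0:
        v.append("auc_floor must be in [0.5, 1]")
    if not 0.0 < config.calibration_fraction < 1.0:
        v.append("calibration_fraction must be in (0, 1)")
    if config.n_repetitions < 1:
        v.append("n_repetitions must be >= 1")
    if config.buffer_cells < 0:
        v.append("buffer_cells must be >= 0")
    if len(config.families) < 1:
        v.append("at least one model family is required")
    edges = np.asarray(config.class_edges, dtype=float)
    if edges.size < 1 or np.any(np.diff(edges) <= 0):
        v.append("class_edges must be strictly increasing")
    return v


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending entity."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _stage_seeds(master_seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(master_seed).generate_state(8)
    names = ("climate", "soil", "species", "protected_areas", "regions",
             "enm", "spare1", "spare2")
    return {n: int(s) for n, s in zip(names, state)}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    """Generate the synthetic study system and persist every layer."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    grid = config.grid()
    climate = synthetic.simulate_climate(
        grid, synthetic.default_gradients(config.warming), seeds["climate"])
    soil = synthetic.simulate_soil(grid, seeds["soil"])
    species, occurrences = synthetic.simulate_species(
        grid, climate, n_per_taxon=config.n_per_taxon,
        sampling_rate=config.sampling_rate, seed=seeds["species"], soil=soil)
    pa_set = synthetic.simulate_protected_areas(
        grid, config.pa_count, median_area=config.pa_median_area,
        sigma_log=config.pa_sigma_log, size_cap=config.pa_size_cap,
        seed=seeds["protected_areas"])
    hierarchy = synthetic.simulate_region_hierarchy(
        grid, config.n_provinces, config.n_regions_per_province,
        seed=seeds["regions"], method=config.hierarchy_method)

    synthetic.write_climate(climate, outdir / "climate.csv")
    soil.to_csv(outdir / "soil.csv", index=False)
    synthetic.write_occurrences(occurrences, outdir / "occurrences.csv")
    synthetic.write_protected_areas(pa_set,
                                    outdir / "protected_areas.geojson")
    synthetic.write_region_hierarchy(hierarchy, outdir / "regions.csv")
    with open(outdir / "species.json", "w") as fh:
        json.dump([{
            "species_id": sp.species_id, "taxon": sp.taxon,
            "optima": sp.optima, "breadths": sp.breadths, "skew": sp.skew,
            "soil_preference":
                {k: list(v) for k, v in sp.soil_preference.items()}
                if sp.soil_preference else None,
            "sampling_rate": sp.sampling_rate,
        } for sp in species], fh, indent=1)
    return {"n_species": len(species), "n_cells": grid.n_cells,
            "n_protected_areas": len(pa_set),
            "share_below_cap": pa_set.share_below_cap()}


def stage_predictors(config: RunConfig, outdir: Path) -> dict:
    """Screen climate predictors per taxon from the persisted climate."""
    outdir = Path(outdir)
    grid = config.grid()
    climate = synthetic.read_climate(outdir / "climate.csv", grid)
    layers = climate.frame(REFERENCE)
    priority = config.predictor_priority or None
    sets = {taxon: predictors.select_predictors(
                layers, taxon, threshold=config.correlation_threshold,
                priority=priority, max_vars=config.max_vars)
            for taxon in synthetic.TAXA}
    report = predictors.predictor_report(sets)
    report.to_csv(outdir / "predictor_report.csv", index=False)
    return {"retained": {t: list(s.retained) for t, s in sets.items()}}


def _load_predictor_sets(config: RunConfig, outdir: Path,
                         climate) -> dict[str, predictors.PredictorSet]:
    report = pd.read_csv(outdir / "predictor_report.csv")
    layers = climate.frame(REFERENCE)
    sets = {}
    for taxon, sub in report.groupby("taxon"):
        climate_vars = tuple(
            sub[sub["kind"] == "climate"].sort_values("rank")["variable"])
        cats = tuple(sub[sub["kind"] == "categorical"]["variable"])
        corr = predictors.pairwise_correlation(layers)
        sets[taxon] = predictors.PredictorSet(
            taxon=taxon, retained=climate_vars, correlation=corr,
            threshold=config.correlation_threshold, categorical=cats)
    return sets


def stage_model(config: RunConfig, outdir: Path) -> dict:
    """Fit per-species ensembles and persist suitability/presence maps."""
    outdir = Path(outdir)
    seeds = _stage_seeds(config.seed)
    grid = config.grid()
    climate = synthetic.read_climate(outdir / "climate.csv", grid)
    soil = pd.read_csv(outdir / "soil.csv")
    occurrences = pd.read_csv(outdir / "occurrences.csv")
    with open(outdir / "species.json") as fh:
        taxon_of = {d["species_id"]: d["taxon"] for d in json.load(fh)}
    psets = _load_predictor_sets(config, outdir, climate)

    species_ids = sorted(occurrences["species_id"].unique())
    if not species_ids:
        raise PipelineError("model", "no species in occurrence table")
    sp_seeds = np.random.SeedSequence(seeds["enm"]).generate_state(
        len(species_ids))
    results = []
    for sid, sseed in zip(species_ids, sp_seeds):
        taxon = taxon_of.get(sid)
        if taxon is None:
            raise PipelineError("model", f"species {sid} missing from "
                                "species.json")
        sub = occurrences[occurrences["species_id"] == sid]
        presence = np.zeros(grid.n_cells, dtype=np.int8)
        presence[sub["cell_id"].to_numpy()] = sub["presence"].to_numpy()
        res = enm.model_species(
            sid, taxon, presence, grid, climate, psets[taxon], soil=soil,
            families=tuple(config.families),
            n_repetitions=config.n_repetitions,
            buffer_cells=config.buffer_cells, auc_floor=config.auc_floor,
            calibration_fraction=config.calibration_fraction,
            min_presences=config.min_presences, seed=int(sseed))
        results.append(res)
        log.info("species %s (%s): %s", sid, taxon, res.status)

    enm.maps_to_long(results).to_csv(outdir / "suitability.csv", index=False)
    reports = [r.member_report() for r in results if r.members]
    member_report = (pd.concat(reports, ignore_index=True) if reports
                     else pd.DataFrame(columns=["species_id", "family",
                                                "repetition", "auc"]))
    member_report.to_csv(outdir / "model_report.csv", index=False)
    skipped = {r.species_id: r.reason for r in results
               if r.status == "skipped"}
    with open(outdir / "model_status.json", "w") as fh:
        json.dump({"modelled": [r.species_id for r in results
                                if r.status == "modelled"],
                   "skipped": skipped}, fh, indent=1)
    return {"n_modelled": sum(r.status == "modelled" for r in results),
            "skipped": skipped}


def stage_overlay(config: RunConfig, outdir: Path) -> dict:
    """Resolve protected areas against the grid."""
    outdir = Path(outdir)
    grid = config.grid()
    areas = synthetic.read_protected_areas(
        outdir / "protected_areas.geojson")
    index = overlay.build_overlay(areas, grid)
    index.to_frame().to_csv(outdir / "overlay_index.csv", index=False)
    index.protected_land_frame().to_csv(outdir / "protected_land.csv",
                                        index=False)
    return {"n_protected_areas": len(index.covering),
            "n_dropped": len(index.dropped),
            "total_protected_km2": float(index.protected_land.sum())}


def _load_presence_matrices(outdir: Path, n_cells: int
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    suit = pd.read_csv(outdir / "suitability.csv")
    mats = {}
    for period in (REFERENCE, FUTURE):
        sub = suit[suit["period"] == period]
        mats[period] = sub.pivot(index="species_id", columns="cell_id",
                                 values="presence").reindex(
                                     columns=range(n_cells)).fillna(0)
    ref, fut = mats[REFERENCE], mats[FUTURE]
    return ref, fut.reindex(index=ref.index)


def stage_metrics(config: RunConfig, outdir: Path) -> dict:
    """Impact statistics over PAs, protected land and species."""
    outdir = Path(outdir)
    grid = config.grid()
    areas = synthetic.read_protected_areas(
        outdir / "protected_areas.geojson")
    index = overlay.build_overlay(areas, grid)
    hierarchy = synthetic.read_region_hierarchy(outdir / "regions.csv")
    ref, fut = _load_presence_matrices(outdir, grid.n_cells)
    if ref.empty:
        raise PipelineError("metrics", "no modelled species maps found")

    impacts = metrics.impact_table(index, hierarchy, ref, fut)
    impacts.to_csv(outdir / "pa_impacts.csv", index=False)

    protection = metrics.protection_change_table(ref, fut,
                                                 index.protected_land)
    protection.to_csv(outdir / "protection_change.csv", index=False)

    # per-cell metric layers weighted by protected land (Fig.-1-style)
    cell_rows = []
    edges = np.asarray(config.class_edges, dtype=float)
    ref_sr = ref.to_numpy().sum(axis=0)
    gain = ((fut.to_numpy() == 1) & (ref.to_numpy() == 0)).sum(axis=0)
    loss = ((ref.to_numpy() == 1) & (fut.to_numpy() == 0)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cell_rG = np.where(ref_sr > 0, 100.0 * gain / ref_sr, np.nan)
        cell_rL = np.where(ref_sr > 0, 100.0 * loss / ref_sr, np.nan)
        cell_T = np.where(ref_sr + gain > 0,
                          100.0 * (gain + loss) / (ref_sr + gain), np.nan)
    for name, vals in (("rG", cell_rG), ("rL", cell_rL), ("T", cell_T)):
        dist = metrics.land_area_distribution(vals, index.protected_land,
                                              edges)
        dist.insert(0, "metric", name)
        cell_rows.append(dist)
    pd.concat(cell_rows, ignore_index=True).to_csv(
        outdir / "land_distributions.csv", index=False)

    # paired comparisons across periods
    summary: dict[str, object] = {}
    rich_test = metrics.compare_periods(impacts["refSR"].to_numpy(float),
                                        impacts["futureSR"].to_numpy(float))
    summary["richness_test"] = dataclasses.asdict(rich_test)
    for scale in metrics.SCALES:
        a = impacts[f"repr_{scale}_reference"].to_numpy(float)
        b = impacts[f"repr_{scale}_future"].to_numpy(float)
        ok = ~np.isnan(a) & ~np.isnan(b)
        if ok.sum() >= 2:
            summary[f"representativity_test_{scale}"] = dataclasses.asdict(
                metrics.compare_periods(a[ok], b[ok]))
    for col in ("rG", "rL", "T"):
        vals = impacts[col].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        if vals.size:
            summary[f"{col}_summary"] = dataclasses.asdict(
                metrics.summarize(vals))
    d = protection.loc[~protection["excluded"], "dPR"].to_numpy(float)
    if d.size:
        summary["dPR_summary"] = dataclasses.asdict(metrics.summarize(d))
    summary["n_pa_losing_richness"] = int(
        (impacts["futureSR"] < impacts["refSR"]).sum())
    summary["n_species_excluded_dPR"] = int(protection["excluded"].sum())
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


STAGES = ("simulate", "predictors", "model", "overlay", "metrics")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage in order; write a self-describing run report."""
    violations = validate_config(config)
    if violations:
        raise PipelineError("validate", "; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report: dict[str, object] = {"config": config.to_dict(),
                                 "stages": {}}
    funcs = {"simulate": stage_simulate, "predictors": stage_predictors,
             "model": stage_model, "overlay": stage_overlay,
             "metrics": stage_metrics}
    for name in STAGES:
        log.info("running stage %s", name)
        try:
            report["stages"][name] = funcs[name](config, outdir)
        except PipelineError:
            raise
        except Exception as exc:  # annotate with the failing stage
            raise PipelineError(name, str(exc)) from exc
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
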