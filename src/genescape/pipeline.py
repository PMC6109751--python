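"""Config-driven orchestration of the full genetic-landscape analysis.

Stages (read -> filter -> statistics -> normalization -> landscapes ->
clip -> hotspots -> unified report -> optional SGDC) are plain functions
that read and write files in an artifact directory, so the CLI subcommands
compose: running them in sequence is identical to ``run_pipeline``. Every
run writes a ``run_log.json`` with the package version, a config hash, stage
counts and warnings; identical inputs and config reproduce identical
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hotspots import classify_sd, extract_hotspots, hotspot_report
from .io_formats import (ValidationError, apply_inclusion_filters,
                         read_geojson_regions, read_species_diversity_csv,
                         read_study, write_raster)
from .landscape import (GeneticLandscape, GridSpec, divergence_midpoints,
                        diversity_points, idw_interpolate,
                        multi_species_average, clip_to_boundary)
from .popgen_stats import compute_species_estimates, normalize_by_species_max
from .sgdc import aggregate_by_region, correlation_table, geographic_regression
from .synthetic_data import (SimulationConfig, generate_region_grid,
                             generate_study, save_regions, save_study)

log = logging.getLogger(__name__)

STATISTICS = ("divergence", "gene_diversity", "sequence_diversity")
_VALUE_COLUMNS = {"gene_diversity": "gene_diversity_norm",
                  "sequence_diversity": "sequence_diversity_norm"}


@dataclass
class PipelineConfig:
    """All analysis parameters; defaults follow the reference protocol
    (inclusion thresholds 10 populations / 3 individuals, IDW power 2 with a
    12-point variable search radius, hotspot threshold mean + 1.5 sd)."""

    population_csv: str | None = None
    manifest_csv: str | None = None
    boundary_geojson: str | None = None
    regions_geojson: str | None = None
    species_diversity_csv: str | None = None

    min_populations: int = 10
    min_individuals: int = 3

    grid_cell_size: float = 0.02
    grid_bounds: tuple[float, float, float, float] | None = None
    crs: str = "planar"
    metric: str | None = None          # default: natural metric of the crs

    idw_power: float = 2.0
    idw_k_neighbors: int = 12

    sd_threshold_multiplier: float = 1.5
    connectivity: int = 8
    min_cells: int = 1
    merge_distance: float = 0.0

    fst_mode: str | None = None        # None = per-marker default
    unbiased_he: bool = True
    region_aggregation: str = "raster"
    keep_intermediate: bool = False

    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "grid_bounds" in raw and raw["grid_bounds"] is not None:
            raw["grid_bounds"] = tuple(raw["grid_bounds"])
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


class RunLog:
    def __init__(self, config: PipelineConfig, outdir: Path) -> None:
        self.payload = {"genescape_version": __version__,
                        "config_hash": config.config_hash(),
                        "config": dataclasses.asdict(config),
                        "stages": {}, "warnings": []}
        self.path = outdir / "run_log.json"

    def record(self, stage: str, **counts) -> None:
        self.payload["stages"][stage] = counts
        log.info("stage %s: %s", stage, counts)

    def warn(self, message: str) -> None:
        self.payload["warnings"].append(message)

    def write(self) -> None:
        self.path.write_text(json.dumps(self.payload, indent=1, sort_keys=True,
                                        default=str))


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, outdir: str | Path) -> Path:
    """Generate a synthetic study into ``<outdir>/input``."""
    outdir = Path(outdir)
    sim_kwargs = dict(config.simulate)
    sim_kwargs.setdefault("seed", config.seed)
    sim = SimulationConfig(**sim_kwargs)
    datasets, records, truth = generate_study(sim)
    indir = outdir / "input"
    save_study(datasets, records, truth, indir)
    region_set, sd_table = generate_region_grid(
        sim, n_regions=25, sd_coupling=0.9, seed=sim.seed + 1)
    save_regions(region_set, sd_table, indir)
    return indir


def stage_stats(config: PipelineConfig, outdir: str | Path) -> None:
    """Read, filter, compute and normalize all statistics; write CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets, records = read_study(config.population_csv, config.manifest_csv)
    datasets, records, report = apply_inclusion_filters(
        datasets, records, config.min_populations, config.min_individuals)
    report.to_frame().to_csv(outdir / "filter_report.csv", index=False)

    coords = {(r.species_id, r.population_id): r for r in records}
    within_frames, pair_frames = [], []
    for ds in datasets:
        within, pairwise = compute_species_estimates(
            ds, fst_mode=config.fst_mode, unbiased_he=config.unbiased_he)
        wdf, fst_norm = normalize_by_species_max(within, pairwise)
        wdf["lon"] = [coords[(r, p)].lon for r, p in
                      zip(wdf["species_id"], wdf["population_id"])]
        wdf["lat"] = [coords[(r, p)].lat for r, p in
                      zip(wdf["species_id"], wdf["population_id"])]
        within_frames.append(wdf)
        pair_frames.append(pairwise.to_frame(normalized=fst_norm))

    cols = ["species_id", "marker_id", "population_id", "lon", "lat",
            "gene_diversity", "gene_diversity_norm",
            "sequence_diversity", "sequence_diversity_norm"]
    pd.concat(within_frames)[cols].to_csv(
        outdir / "within_pop_diversity.csv", index=False)
    pd.concat(pair_frames).to_csv(outdir / "pairwise_fst.csv", index=False)
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        outdir / "populations_retained.csv", index=False)


def _grid_spec(config: PipelineConfig, records: pd.DataFrame) -> GridSpec:
    if config.grid_bounds is not None:
        xmin, ymin, xmax, ymax = config.grid_bounds
    else:
        pad = 2 * config.grid_cell_size
        xmin, xmax = records["lon"].min() - pad, records["lon"].max() + pad
        ymin, ymax = records["lat"].min() - pad, records["lat"].max() + pad
    return GridSpec.from_bounds(xmin, ymin, xmax, ymax,
                                config.grid_cell_size, crs=config.crs)


def stage_landscape(config: PipelineConfig, outdir: str | Path) -> None:
    """Interpolate per-species surfaces and average them per statistic."""
    outdir = Path(outdir)
    within = pd.read_csv(outdir / "within_pop_diversity.csv")
    pairs = pd.read_csv(outdir / "pairwise_fst.csv")
    pops = pd.read_csv(outdir / "populations_retained.csv")
    grid = _grid_spec(config, pops)

    rec_by_species = {
        sp: list(g.itertuples(index=False))
        for sp, g in pops.groupby("species_id")
    }
    for statistic in STATISTICS:
        per_species: dict[str, list[GeneticLandscape]] = {}
        if statistic == "divergence":
            for (sp, marker), g in pairs.groupby(["species_id", "marker_id"]):
                points = divergence_midpoints(g, rec_by_species[sp],
                                              metric=config.metric or
                                              ("haversine" if config.crs == "lonlat"
                                               else "planar"))
                if len(points) == 0:
                    continue
                per_species.setdefault(sp, []).append(_idw(config, points, grid,
                                                           statistic, sp))
        else:
            col = _VALUE_COLUMNS[statistic]
            for (sp, marker), g in within.groupby(["species_id", "marker_id"]):
                points = diversity_points(g, rec_by_species[sp], col)
                if len(points) == 0:
                    continue
                per_species.setdefault(sp, []).append(_idw(config, points, grid,
                                                           statistic, sp))
        if not per_species:
            log.warning("no data for %s landscape; skipped", statistic)
            continue
        if config.keep_intermediate:
            for sp, landscapes in per_species.items():
                for i, ls in enumerate(landscapes):
                    write_raster(ls, outdir / f"landscape_{statistic}_{sp}_{i}.asc")
        multi = multi_species_average(per_species)
        if config.boundary_geojson:
            boundary = read_geojson_regions(config.boundary_geojson).boundary
            if boundary is not None:
                multi = clip_to_boundary(multi, boundary)
        write_raster(multi, outdir / f"landscape_{statistic}.asc")


def _idw(config: PipelineConfig, points: np.ndarray, grid: GridSpec,
         statistic: str, species: str) -> GeneticLandscape:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # k reduced for tiny sets
        return idw_interpolate(points, grid, power=config.idw_power,
                               k_neighbors=config.idw_k_neighbors,
                               metric=config.metric, statistic=statistic,
                               species_id=species)


def _load_landscapes(config: PipelineConfig, outdir: Path
                     ) -> dict[str, GeneticLandscape]:
    from .io_formats import read_raster
    out = {}
    for statistic in STATISTICS:
        path = outdir / f"landscape_{statistic}.asc"
        if path.exists():
            out[statistic] = read_raster(path, crs=config.crs, statistic=statistic)
    return out


def stage_hotspots(config: PipelineConfig, outdir: str | Path) -> None:
    """Classify each landscape, extract patches, and unify the layers."""
    outdir = Path(outdir)
    landscapes = _load_landscapes(config, outdir)
    sets = {}
    frames = []
    meta = {}
    for statistic, ls in landscapes.items():
        cls = classify_sd(ls)
        hs = extract_hotspots(cls, ls, connectivity=config.connectivity,
                              min_cells=config.min_cells,
                              merge_distance=config.merge_distance,
                              threshold_multiplier=config.sd_threshold_multiplier)
        sets[statistic] = hs
        frames.append(hs.to_frame())
        meta[statistic] = {"mean": cls.mean, "sd": cls.sd,
                           "threshold": hs.threshold,
                           "n_patches": len(hs.patches),
                           "total_hotspot_area": hs.total_hotspot_area,
                           "fraction_of_analyzed_area": hs.fraction_of_analyzed_area}
        mask = GeneticLandscape(ls.grid,
                                np.where(ls.mask,
                                         hs.flagged_mask(ls.values.shape)
                                         .astype(float), np.nan),
                                statistic=statistic)
        write_raster(mask, outdir / f"hotspot_mask_{statistic}.asc")
    pd.concat(frames, ignore_index=True).to_csv(outdir / "hotspots.csv", index=False)
    hotspot_report(sets).to_csv(outdir / "hotspot_report.csv", index=False)
    (outdir / "hotspot_summary.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True))


def stage_sgdc(config: PipelineConfig, outdir: str | Path) -> None:
    """Regional aggregation, SGDC correlations, geographic regressions."""
    outdir = Path(outdir)
    if not config.regions_geojson or not config.species_diversity_csv:
        log.info("no region inputs; SGDC stage skipped")
        return
    landscapes = _load_landscapes(config, outdir)
    regions = read_geojson_regions(config.regions_geojson)
    sd_table = read_species_diversity_csv(config.species_diversity_csv, regions)
    summaries = aggregate_by_region(landscapes, regions, sd_table,
                                    mode=config.region_aggregation)
    summaries.to_csv(outdir / "region_summaries.csv", index=False)
    correlation_table(summaries).to_csv(outdir / "sgdc_correlations.csv")
    reg_rows = []
    for response in ("agd", "wgd_gene", "wgd_seq"):
        if response not in summaries.columns:
            continue
        for predictor in ("lon", "lat"):
            try:
                fit = geographic_regression(summaries, response, predictor)
            except ValueError as exc:
                log.warning("regression %s~%s skipped: %s", response, predictor, exc)
                continue
            reg_rows.append(dataclasses.asdict(fit))
    pd.DataFrame(reg_rows).to_csv(outdir / "geographic_regressions.csv", index=False)


def build_landscapes(sim: SimulationConfig, grid_n: int = 60,
                     idw_power: float = 2.0, idw_k: int = 12
                     ) -> dict[str, GeneticLandscape]:
    """In-memory path from a synthetic study to the three averaged landscapes."""
    datasets, records, _ = generate_study(sim)
    rec_by_species: dict[str, list] = {}
    for r in records:
        rec_by_species.setdefault(r.species_id, []).append(r)
    xmin, ymin, xmax, ymax = sim.domain
    grid = GridSpec(xmin, ymin, (xmax - xmin) / grid_n, grid_n, grid_n,
                    crs=sim.crs)
    per_stat: dict[str, dict[str, list[GeneticLandscape]]] = {
        s: {} for s in STATISTICS}
    for ds in datasets:
        within, pairwise = compute_species_estimates(ds)
        wdf, fst_norm = normalize_by_species_max(within, pairwise)
        recs = rec_by_species[ds.species_id]
        pts = divergence_midpoints(pairwise.to_frame(normalized=fst_norm), recs,
                                   metric="haversine" if sim.crs == "lonlat"
                                   else "planar")
        per_stat["divergence"].setdefault(ds.species_id, []).append(
            idw_interpolate(pts, grid, power=idw_power, k_neighbors=idw_k,
                            statistic="divergence", species_id=ds.species_id))
        for statistic, col in _VALUE_COLUMNS.items():
            pts = diversity_points(wdf, recs, col)
            if len(pts) == 0:
                continue
            per_stat[statistic].setdefault(ds.species_id, []).append(
                idw_interpolate(pts, grid, power=idw_power, k_neighbors=idw_k,
                                statistic=statistic, species_id=ds.species_id))
    return {s: multi_species_average(sp) for s, sp in per_stat.items() if sp}


def planted_recovery(sim: SimulationConfig, grid_n: int = 60,
                     radius_multiplier: float = 1.5) -> dict[str, bool]:
    """Score one replicate of the planted-structure recovery check.

    The divergence landscape must contain a hotspot patch whose centroid
    lies within ``radius_multiplier`` bump radii of the barrier midline; for
    each planted bump, one of the two within-population diversity layers
    (gene diversity or sequence diversity — both measure WGD, and the
    unified report treats their patches as one hotspot system) must contain
    a hotspot patch whose centroid lies within that distance of the bump
    center.
    """
    landscapes = build_landscapes(sim, grid_n=grid_n)
    sets = {s: extract_hotspots(classify_sd(ls), ls)
            for s, ls in landscapes.items()}
    tol = radius_multiplier * float(np.mean([b.radius for b in
                                             sim.diversity_bumps]))
    barrier_hit = any(
        sim.barrier.distance(*p.centroid) <= tol
        for p in sets["divergence"].patches)
    out = {"barrier": barrier_hit}
    for i, bump in enumerate(sim.diversity_bumps):
        hit = any(
            math.hypot(p.centroid[0] - bump.center[0],
                       p.centroid[1] - bump.center[1])
            <= radius_multiplier * bump.radius
            for layer in ("gene_diversity", "sequence_diversity")
            if layer in sets
            for p in sets[layer].patches)
        out[f"bump_{i}"] = hit
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage in order; abort with the failing stage's name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runlog = RunLog(config, outdir)
    stages = [("stats", stage_stats), ("landscape", stage_landscape),
              ("hotspots", stage_hotspots), ("sgdc", stage_sgdc)]
    if config.population_csv is None:
        indir = stage_simulate(config, outdir)
        config.population_csv = str(indir / "populations.csv")
        config.manifest_csv = str(indir / "manifest.csv")
        if (indir / "regions.geojson").exists():
            config.regions_geojson = str(indir / "regions.geojson")
            config.species_diversity_csv = str(indir / "species_diversity.csv")
        runlog.record("simulate", input_dir=str(indir))
    for name, fn in stages:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fn(config, outdir)
            for w in caught:
                runlog.warn(f"{name}: {w.message}")
            runlog.record(name, done=True)
        except Exception as exc:
            failed = outdir / "failed"
            failed.mkdir(exist_ok=True)
            (failed / "stage.txt").write_text(f"{name}: {exc}\n")
            runlog.record(name, error=str(exc))
            runlog.write()
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    runlog.write()
    return outdir
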