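"""End-to-end orchestration: simulate -> bioclim -> fit -> project -> dispersal -> summarize.

Each stage reads its inputs from, and writes its outputs to, a run directory,
and records a hash chained over the configuration subset that affects it plus
its upstream hashes.  A re-run with an unchanged configuration finds matching
hashes and skips every stage, so the expensive steps (model fitting and the
per-realization projections) are never recomputed needlessly; the manifest is
rebuilt deterministically from the configuration alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth
from .bioclim import BIOCLIM_VARS, ClimateStack, derive_bioclim
from .dispersal import (
    SCENARIOS,
    BinaryRange,
    apply_scenario,
    binarize,
    build_masks,
    realistic_scenario,
    realized_from_potential,
)
from .errors import InvalidParameterError, SchemaError
from .grids import GridSpec, read_raster, write_raster
from .maxent import (
    MaxentSDM,
    SuitabilityMap,
    build_background,
    entropy_equating_threshold,
    fit_species,
    predict_logistic,
    screen,
)
from .ensemble import climate_change_map, ensemble_summary, project_all
from .summaries import (
    assemblage_summary,
    class_stats,
    group_comparison,
    proportional_change,
    richness_change,
    richness_stack,
)

logger = logging.getLogger("rangeshift")

STAGES = ("simulate", "bioclim", "fit", "project", "dispersal", "summarize")
ALL_SCENARIOS = (*SCENARIOS, "realistic")


@dataclass
class RunConfig:
    """Every knob of one pipeline run; round-trips through YAML unchanged."""

    seed: int = 1
    grid: dict = field(default_factory=lambda: {"n_rows": 60, "n_cols": 80, "cell_size_km": 5.0})
    climate: dict = field(default_factory=dict)
    gcms: list = field(default_factory=list)
    decades: list = field(default_factory=lambda: list(range(1990, 2090, 10)))
    n_regions: int = 12
    species: list = field(default_factory=list)
    n_occurrences_per_species: int = 230
    max_presence_cells: int = 200
    n_background: int = 10_000
    beta_multiplier: float = 0.001
    auc_threshold: float = 0.7
    dispersal_rate_km_per_year: float = 3.0
    connectivity: int = 8
    ts_convention: str = "percent_of_mean"
    none_level: str = "cell"

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.decades[1:], self.decades)):
            raise InvalidParameterError("decades must be strictly increasing")
        for sp in self.species:
            if "meta" not in sp or "species_id" not in sp:
                raise SchemaError("every species entry needs species_id and meta")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- derived helpers ---------------------------------------------------
    def grid_spec(self) -> GridSpec:
        return GridSpec(**self.grid)

    def gcm_specs(self) -> list[synth.GcmSpec]:
        return [synth.GcmSpec(**g) for g in self.gcms]

    def species_meta(self, sp: dict) -> synth.SpeciesMeta:
        return synth.SpeciesMeta(species_id=sp["species_id"], **sp["meta"])

    def rng_seed(self, tag: int) -> list[int]:
        """A named child seed; pass to np.random.default_rng."""
        return [int(self.seed), int(tag)]


# seed tags for the independent randomness sources
_TAG_CLIMATE, _TAG_FUTURE, _TAG_MOSAIC, _TAG_BACKGROUND = 1, 2, 3, 4
_TAG_OCC, _TAG_SUBSAMPLE = 100, 200


# ---------------------------------------------------------------------------
# hashing / caching


def _stage_config_subset(config: RunConfig, stage: str) -> dict:
    c = config.to_dict()
    common = {"seed": c["seed"], "grid": c["grid"], "decades": c["decades"]}
    per_stage = {
        "simulate": {
            "climate": c["climate"], "gcms": c["gcms"], "n_regions": c["n_regions"],
            "species": c["species"], "n_occurrences": c["n_occurrences_per_species"],
        },
        "bioclim": {"ts_convention": c["ts_convention"]},
        "fit": {
            "max_presence_cells": c["max_presence_cells"],
            "n_background": c["n_background"], "beta_multiplier": c["beta_multiplier"],
        },
        "project": {},
        "dispersal": {
            "rate": c["dispersal_rate_km_per_year"], "none_level": c["none_level"],
        },
        "summarize": {"auc_threshold": c["auc_threshold"], "connectivity": c["connectivity"]},
    }
    return {**common, **per_stage[stage]}


def stage_hashes(config: RunConfig) -> dict[str, str]:
    """Chained content hash per stage (each includes its upstream hash)."""
    hashes: dict[str, str] = {}
    prev = ""
    for stage in STAGES:
        blob = json.dumps(_stage_config_subset(config, stage), sort_keys=True) + prev
        prev = hashlib.sha256(blob.encode()).hexdigest()
        hashes[stage] = prev
    return hashes


def _is_current(out: Path, stage: str, want: str) -> bool:
    f = out / f".hash_{stage}"
    return f.exists() and f.read_text().strip() == want


def _mark_done(out: Path, stage: str, h: str) -> None:
    (out / f".hash_{stage}").write_text(h + "\n")


# ---------------------------------------------------------------------------
# path layout


def _monthly_path(out: Path, key) -> Path:
    if key == "baseline":
        return out / "monthly" / "baseline.tif"
    g, r, d = key
    return out / "monthly" / f"{g}_r{r}_{d}.tif"


def _bioclim_path(out: Path, key) -> Path:
    if key == "baseline":
        return out / "bioclim" / "baseline.tif"
    g, r, d = key
    return out / "bioclim" / f"{g}_r{r}_{d}.tif"


def _future_keys(config: RunConfig) -> list[tuple[str, int, int]]:
    return [
        (g.gcm_id, r, d)
        for g in config.gcm_specs()
        for r in range(1, g.n_realizations + 1)
        for d in config.decades
    ]


def _write_series(path: Path, series: synth.MonthlyClimateSeries) -> None:
    arr = np.concatenate([series.temperature, series.precipitation])
    names = [f"t{m:02d}" for m in range(1, 13)] + [f"p{m:02d}" for m in range(1, 13)]
    write_raster(path, arr, series.grid, names)


def _read_series(path: Path, year_label: int) -> synth.MonthlyClimateSeries:
    arr, grid, _names = read_raster(path)
    return synth.MonthlyClimateSeries(
        temperature=arr[:12], precipitation=arr[12:], grid=grid, year_label=year_label
    )


def _write_binary(path: Path, br: BinaryRange) -> None:
    arr = np.where(br.valid, br.presence.astype(np.float32), np.nan)
    write_raster(path, arr, br.grid, ["presence"])


def _read_binary(path: Path, species_id: str, decade=None, scenario=None, threshold=None) -> BinaryRange:
    arr, grid, _ = read_raster(path)
    valid = np.isfinite(arr[0])
    return BinaryRange(
        presence=valid & (arr[0] >= 0.5), valid=valid, grid=grid,
        species_id=species_id, decade=decade, scenario=scenario, threshold=threshold,
    )


# ---------------------------------------------------------------------------
# stages


def resolve_virtual_species(config: RunConfig, stack: ClimateStack) -> dict[str, synth.VirtualSpecies]:
    """Evaluate every configured virtual species on a bioclim stack.

    Species defined by a grid anchor take their niche center from the
    stack's values at that cell; an ``"entropy"`` prevalence threshold is
    resolved against the resulting suitability surface.
    """
    out: dict[str, synth.VirtualSpecies] = {}
    for sp in config.species:
        center = sp.get("niche_center")
        if center is None:
            r, c = sp["anchor_row"], sp["anchor_col"]
            center = {v: float(getattr(stack, v)[r, c]) for v in BIOCLIM_VARS}
        out[sp["species_id"]] = synth.make_virtual_species(
            center, sp["niche_width"], sp["prevalence_threshold"],
            config.species_meta(sp), stack,
        )
    return out


def stage_simulate(config: RunConfig, out: Path) -> None:
    grid = config.grid_spec()
    baseline = synth.make_monthly_climate(
        grid, seed=config.rng_seed(_TAG_CLIMATE), year_label=config.decades[0],
        **config.climate,
    )
    future = synth.make_future_series(
        baseline, config.gcm_specs(), config.decades, seed=config.rng_seed(_TAG_FUTURE)
    )
    mosaic = synth.make_region_mosaic(grid, config.n_regions, seed=config.rng_seed(_TAG_MOSAIC))

    (out / "monthly").mkdir(parents=True, exist_ok=True)
    _write_series(_monthly_path(out, "baseline"), baseline)
    for key, series in future.items():
        _write_series(_monthly_path(out, key), series)
    write_raster(out / "mosaic.tif", mosaic.labels.astype(np.float32), grid, ["region"])

    # virtual species truth needs the baseline covariates
    stack = derive_bioclim(baseline, ts_convention=config.ts_convention)
    (out / "true").mkdir(exist_ok=True)
    species = resolve_virtual_species(config, stack)
    occ_frames = []
    meta_rows = []
    for i, sp in enumerate(config.species):
        sid = sp["species_id"]
        meta = config.species_meta(sp)
        vs = species[sid]
        center = vs.niche_center
        write_raster(out / "true" / f"{sid}.tif", vs.true_suitability, grid, ["suitability"])
        occ_frames.append(
            synth.sample_occurrences(
                vs.true_suitability, grid, config.n_occurrences_per_species,
                seed=config.rng_seed(_TAG_OCC + i), species_id=sid,
            )
        )
        meta_rows.append(
            {
                "species_id": sid, "movement_class": meta.movement_class,
                "biogeo_group": meta.biogeo_group,
                "dispersal_category": meta.dispersal_category,
                "dispersal_rate_km_per_year": meta.dispersal_rate_km_per_year,
                "status": meta.status,
                "prevalence_threshold": vs.prevalence_threshold,
                "niche_center": json.dumps(center, sort_keys=True),
            }
        )
    pd.concat(occ_frames, ignore_index=True).to_csv(out / "occurrences.csv", index=False)
    pd.DataFrame(meta_rows).to_csv(out / "species_meta.csv", index=False)


def stage_bioclim(config: RunConfig, out: Path) -> None:
    (out / "bioclim").mkdir(parents=True, exist_ok=True)
    keys = ["baseline", *_future_keys(config)]
    for key in keys:
        year = config.decades[0] if key == "baseline" else key[2]
        series = _read_series(_monthly_path(out, key), year)
        stack = derive_bioclim(series, ts_convention=config.ts_convention)
        write_raster(_bioclim_path(out, key), stack.to_array(), stack.grid, list(BIOCLIM_VARS))


def _load_stack(path: Path) -> ClimateStack:
    arr, grid, _ = read_raster(path)
    return ClimateStack.from_array(arr, grid)


def stage_fit(config: RunConfig, out: Path) -> None:
    stack = _load_stack(_bioclim_path(out, "baseline"))
    occ = pd.read_csv(out / "occurrences.csv")
    background = build_background(
        stack, config.n_background, seed=config.rng_seed(_TAG_BACKGROUND)
    )
    (out / "models").mkdir(exist_ok=True)
    (out / "suitability").mkdir(exist_ok=True)
    grid = stack.grid
    for i, sp in enumerate(config.species):
        sid = sp["species_id"]
        pts = occ[occ["species_id"] == sid]
        cells = sorted(
            {
                cell
                for x, y in zip(pts["x"], pts["y"])
                if (cell := grid.point_to_cell(float(x), float(y))) is not None
            }
        )
        if len(cells) > config.max_presence_cells:
            rng = np.random.default_rng(config.rng_seed(_TAG_SUBSAMPLE + i))
            pick = rng.choice(len(cells), size=config.max_presence_cells, replace=False)
            cells = [cells[j] for j in sorted(pick)]
        df = pd.DataFrame(
            {
                "x": [grid.origin_x + (c + 0.5) * grid.cell_size_km for _r, c in cells],
                "y": [grid.origin_y + (r + 0.5) * grid.cell_size_km for r, _c in cells],
            }
        )
        t0 = time.perf_counter()
        model = fit_species(
            df, stack, background, species_id=sid, beta_multiplier=config.beta_multiplier
        )
        smap = predict_logistic(model, stack)
        entropy_equating_threshold(model, smap)
        model.save_json(out / "models" / f"{sid}.json")
        write_raster(out / "suitability" / f"{sid}_baseline.tif", smap.values, grid, ["logistic"])
        logger.info("fit %s: auc=%.3f threshold=%.3f (%.2fs)",
                    sid, model.auc_, model.threshold_logistic_, time.perf_counter() - t0)


def stage_project(config: RunConfig, out: Path) -> None:
    (out / "ensemble").mkdir(exist_ok=True)
    stacks = {key: _load_stack(_bioclim_path(out, key)) for key in _future_keys(config)}

    # climate-change maps between the baseline and the final decade
    (out / "climate_change").mkdir(exist_ok=True)
    baseline = _load_stack(_bioclim_path(out, "baseline"))
    last = config.decades[-1]
    final_stacks = {(g, r): s for (g, r, d), s in stacks.items() if d == last}
    for var in BIOCLIM_VARS:
        change = climate_change_map(var, baseline, final_stacks)
        write_raster(out / "climate_change" / f"{var}.tif", change, baseline.grid, [var])

    for sp in config.species:
        sid = sp["species_id"]
        model = MaxentSDM.load_json(out / "models" / f"{sid}.json")
        pset = project_all(model, stacks)
        summ = ensemble_summary(pset)
        for decade in config.decades:
            for stat, maps in (("mean", summ.mean), ("min", summ.minimum), ("max", summ.maximum)):
                write_raster(
                    out / "ensemble" / f"{sid}_{decade}_{stat}.tif",
                    maps[decade].values, maps[decade].grid, ["suitability"],
                )


def stage_dispersal(config: RunConfig, out: Path) -> None:
    (out / "binary").mkdir(exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    mosaic_arr, grid, _ = read_raster(out / "mosaic.tif")
    mosaic = synth.RegionMosaic(labels=mosaic_arr[0].astype(np.int32), grid=grid)
    occ = pd.read_csv(out / "occurrences.csv")
    n_decades = len(config.decades)
    for sp in config.species:
        sid = sp["species_id"]
        meta = config.species_meta(sp)
        model = MaxentSDM.load_json(out / "models" / f"{sid}.json")
        thr = model.threshold_logistic_
        base_arr, _g, _ = read_raster(out / "suitability" / f"{sid}_baseline.tif")
        pot_current = binarize(
            SuitabilityMap(values=base_arr[0], grid=grid, species_id=sid),
            thr, decade=config.decades[0],
        )
        realized = realized_from_potential(pot_current, mosaic, occ[occ["species_id"] == sid])
        _write_binary(out / "binary" / f"{sid}_current_realized.tif", realized)
        occupied = np.isin(
            mosaic.labels,
            np.unique(mosaic.labels[realized.presence]) if realized.n_cells else [],
        )
        masks = build_masks(realized, config.dispersal_rate_km_per_year, n_decades)
        write_raster(
            out / "masks" / f"{sid}.tif",
            np.stack([np.where(realized.valid, m.astype(np.float32), np.nan) for m in masks.masks]),
            grid, [f"d{i}" for i in range(1, n_decades + 1)],
        )
        for i, decade in enumerate(config.decades, start=1):
            mean_arr, _g, _ = read_raster(out / "ensemble" / f"{sid}_{decade}_mean.tif")
            pot = binarize(
                SuitabilityMap(values=mean_arr[0], grid=grid, species_id=sid,
                               provenance=f"ensemble-mean/{decade}"),
                thr, decade=decade,
            )
            outputs = {}
            for scen in SCENARIOS:
                br = apply_scenario(
                    pot, scen, realized, masks, decade_index=i,
                    none_level=config.none_level, occupied_region_mask=occupied,
                )
                outputs[scen] = br
                _write_binary(out / "binary" / f"{sid}_{decade}_{scen}.tif", br)
            real_br = realistic_scenario(meta, outputs)
            _write_binary(out / "binary" / f"{sid}_{decade}_realistic.tif", real_br)


def stage_summarize(config: RunConfig, out: Path) -> None:
    res = out / "results"
    res.mkdir(exist_ok=True)
    meta_df = pd.read_csv(out / "species_meta.csv")
    species_ids = [sp["species_id"] for sp in config.species]
    models = {sid: MaxentSDM.load_json(out / "models" / f"{sid}.json") for sid in species_ids}
    kept, excluded = screen(models, config.auc_threshold)

    eval_rows = [
        {
            "species_id": sid,
            "auc": models[sid].auc_,
            "threshold_logistic": models[sid].threshold_logistic_,
            "kept": sid in kept,
        }
        for sid in species_ids
    ]
    pd.DataFrame(eval_rows).to_csv(res / "model_evaluation.csv", index=False)

    first, last = config.decades[0], config.decades[-1]
    realized = {
        sid: _read_binary(out / "binary" / f"{sid}_current_realized.tif", sid, first, "realized")
        for sid in species_ids
    }
    final = {
        scen: {
            sid: _read_binary(out / "binary" / f"{sid}_{last}_{scen}.tif", sid, last, scen)
            for sid in species_ids
        }
        for scen in ALL_SCENARIOS
    }

    records = {scen: [] for scen in ALL_SCENARIOS}
    rows = []
    for scen in ALL_SCENARIOS:
        for sid in species_ids:
            if sid not in kept:
                continue
            start_area = realized[sid].area_km2
            if start_area <= 0:
                logger.warning("species %s has empty current range; skipped", sid)
                continue
            rec = proportional_change(
                final[scen][sid].area_km2, start_area, species_id=sid, scenario=scen
            )
            records[scen].append(rec)
            rows.append(
                {
                    "species_id": sid, "scenario": scen,
                    f"area_{first}_km2": rec.area_start_km2,
                    f"area_{last}_km2": rec.area_end_km2,
                    "proportion_of_current": rec.proportion_of_current,
                    "direction": rec.direction,
                }
            )
    pd.DataFrame(rows).to_csv(res / "change_records.csv", index=False)

    summ_rows = [
        {"scenario": scen, **assemblage_summary(records[scen])}
        for scen in ALL_SCENARIOS
        if records[scen]
    ]
    pd.DataFrame(summ_rows).to_csv(res / "assemblage_summary.csv", index=False)

    group_rows = []
    for grouping in ("movement_class", "biogeo_group"):
        groups = dict(zip(meta_df["species_id"], meta_df[grouping]))
        try:
            table, f_stat, p_val = group_comparison(records["realistic"], groups)
        except InvalidParameterError:
            continue
        for _, row in table.iterrows():
            group_rows.append(
                {"grouping": grouping, **row.to_dict(), "F": f_stat, "p": p_val,
                 "df1": len(table) - 1,
                 "df2": int(table["n"].sum()) - len(table)}
            )
    pd.DataFrame(group_rows).to_csv(res / "group_comparison.csv", index=False)

    stat_rows = []
    for sid in species_ids:
        for label, br in (("current_realized", realized[sid]),
                          *((f"{last}_{scen}", final[scen][sid]) for scen in ALL_SCENARIOS)):
            st = class_stats(br, connectivity=config.connectivity)
            stat_rows.append(
                {"species_id": sid, "range": label, "total_area_km2": st.total_area_km2,
                 "n_patches": st.n_patches, "proportion_landscape": st.proportion_landscape,
                 "mean_patch_area_km2": st.mean_patch_area_km2,
                 "edge_length_km": st.edge_length_km}
            )
    pd.DataFrame(stat_rows).to_csv(res / "range_stats.csv", index=False)

    # richness: current realized ranges are the shared start; every species
    # counts, including the low-AUC screened ones
    rich_start = richness_stack(list(realized.values()), decade=first, scenario="current")
    write_raster(res / f"richness_{first}_current.tif",
                 rich_start.counts.astype(np.float32), rich_start.grid, ["richness"])
    for scen in ALL_SCENARIOS:
        rich_end = richness_stack(list(final[scen].values()), decade=last, scenario=scen)
        change = richness_change(rich_start, rich_end)
        write_raster(res / f"richness_{last}_{scen}.tif",
                     rich_end.counts.astype(np.float32), rich_end.grid, ["richness"])
        write_raster(res / f"richness_change_{scen}.tif",
                     change.astype(np.float32), rich_end.grid, ["change"])


# ---------------------------------------------------------------------------
# driver


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "bioclim": stage_bioclim,
    "fit": stage_fit,
    "project": stage_project,
    "dispersal": stage_dispersal,
    "summarize": stage_summarize,
}


def expected_manifest(config: RunConfig, out: Path) -> list[dict]:
    """The artifact list a completed run produces, derived from config alone."""
    first, last = config.decades[0], config.decades[-1]
    entries: list[dict] = []

    def add(stage, path, **extra):
        entries.append({"stage": stage, "path": str(Path(path).relative_to(out)), **extra})

    add("simulate", _monthly_path(out, "baseline"))
    for key in _future_keys(config):
        add("simulate", _monthly_path(out, key), gcm=key[0], realization=key[1], decade=key[2])
    add("simulate", out / "mosaic.tif")
    add("simulate", out / "occurrences.csv")
    add("simulate", out / "species_meta.csv")
    for sp in config.species:
        add("simulate", out / "true" / f"{sp['species_id']}.tif", species=sp["species_id"])
    add("bioclim", _bioclim_path(out, "baseline"))
    for key in _future_keys(config):
        add("bioclim", _bioclim_path(out, key), gcm=key[0], realization=key[1], decade=key[2])
    for var in BIOCLIM_VARS:
        add("project", out / "climate_change" / f"{var}.tif", variable=var)
    for sp in config.species:
        sid = sp["species_id"]
        add("fit", out / "models" / f"{sid}.json", species=sid)
        add("fit", out / "suitability" / f"{sid}_baseline.tif", species=sid)
        for decade in config.decades:
            for stat in ("mean", "min", "max"):
                add("project", out / "ensemble" / f"{sid}_{decade}_{stat}.tif",
                    species=sid, decade=decade, statistic=stat)
        add("dispersal", out / "binary" / f"{sid}_current_realized.tif", species=sid)
        add("dispersal", out / "masks" / f"{sid}.tif", species=sid)
        for decade in config.decades:
            for scen in ALL_SCENARIOS:
                add("dispersal", out / "binary" / f"{sid}_{decade}_{scen}.tif",
                    species=sid, decade=decade, scenario=scen)
    for name in ("model_evaluation.csv", "change_records.csv", "assemblage_summary.csv",
                 "group_comparison.csv", "range_stats.csv"):
        add("summarize", out / "results" / name)
    add("summarize", out / "results" / f"richness_{first}_current.tif", decade=first)
    for scen in ALL_SCENARIOS:
        add("summarize", out / "results" / f"richness_{last}_{scen}.tif", decade=last, scenario=scen)
        add("summarize", out / "results" / f"richness_change_{scen}.tif", scenario=scen)
    return entries


def run(config: RunConfig, out_dir, force: bool = False) -> list[dict]:
    """Execute the pipeline, skipping stages whose outputs are current.

    Returns the artifact manifest (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    hashes = stage_hashes(config)
    for stage in STAGES:
        if not force and _is_current(out, stage, hashes[stage]):
            logger.info("stage %s up to date; skipped", stage)
            continue
        t0 = time.perf_counter()
        logger.info("stage %s: running", stage)
        try:
            _STAGE_FUNCS[stage](config, out)
        except Exception:
            logger.error("stage %s failed", stage)
            raise
        _mark_done(out, stage, hashes[stage])
        logger.info("stage %s: done in %.1fs", stage, time.perf_counter() - t0)
    manifest = expected_manifest(config, out)
    missing = [e["path"] for e in manifest if not (out / e["path"]).exists()]
    if missing:
        raise MissingArtifactError(missing)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


class MissingArtifactError(RuntimeError):
    def __init__(self, missing):
        super().__init__(f"{len(missing)} expected artifacts missing, e.g. {missing[:3]}")
        self.missing = missing
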