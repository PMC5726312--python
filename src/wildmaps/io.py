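"""File formats, run configuration and the end-to-end pipeline.

Formats
-------
* Rasters (pressure grids, realm maps): ESRI ASCII grid (``.asc``) — a
  plain-text single-band raster with explicit ``NODATA_value``; cell area is
  derived from the header ``cellsize`` (metres) when not supplied.
* Vector maps (wilderness / Last of the Wild blocks): GeoJSON, one polygon
  feature per block with attributes ``block_id``, ``area_km2``, ``realm_id``,
  ``epoch``, ``variant``; geometries are the dissolved cell squares.
* Tables (plots, thresholds, block inventories): CSV via pandas.
* Reports and the run manifest: JSON.

The pipeline runs the full workflow — simulate or load inputs, map
pressure-free lands for both epochs, compute thresholds, build the three
Last of the Wild maps, validate against plots — and writes a manifest with a
content hash per output so a rerun with the same config and seed is
verifiably identical.
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
from shapely.geometry import box, mapping, shape as shapely_shape
from shapely.ops import unary_union

from . import __version__
from .grid_core import (
    AGREEMENT_TOLERANCE,
    DEFAULT_CONNECTIVITY,
    DEFAULT_NODATA,
    LOW_FRACTION,
    LOW_TOP_K,
    MIN_BLOCK_AREA_KM2,
    SCORE_MAX,
    Block,
    GridError,
    PressureGrid,
    RealmMap,
)
from .last_of_wild import LowSuite, ThresholdEntry, ThresholdTable, build_low_suite
from .pressure_free import map_pressure_free, map_pressure_free_comparable
from .synthetic import (
    SimConfig,
    generate_grid_pair,
    generate_realm_partition,
    generate_validation_plots,
)
from .validation import (
    ValidationPlot,
    filter_certain,
    overlay_hfp,
    score_agreement,
    validate_low_map,
    validate_wilderness_map,
)

logger = logging.getLogger("wildmaps")

# Product file stems of the standard five-map inventory.
MAP_PRODUCT_STEMS = (
    "Pressure_free_lands_93",
    "Pressure_free_lands_09",
    "LoW_1993",
    "LoW_2009_comparable",
    "LoW_2009_current",
)


# ---------------------------------------------------------------- rasters

def write_ascii_grid(grid: PressureGrid, path: str | Path) -> Path:
    """Write a grid as an ESRI ASCII raster (top row first)."""
    path = Path(path)
    nrows, ncols = grid.shape
    cellsize = grid.cellsize_m
    if cellsize is None:
        area = np.asarray(grid.cell_area_km2, dtype=float)
        if area.ndim != 0:
            raise GridError("ASCII grid needs a uniform cell area or cellsize")
        cellsize = float(np.sqrt(area) * 1000.0)
    with path.open("w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.xll}\n")
        fh.write(f"yllcorner {grid.yll}\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {grid.nodata_value}\n")
        np.savetxt(fh, grid.scores, fmt="%d")
    return path


def read_ascii_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII raster into an integer array plus its header."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, ndmin=2)
    arr = data.astype(np.int64)
    if not np.array_equal(arr, data):
        raise GridError(f"{path}: raster values are not integer-representable")
    nrows = int(header.get("nrows", arr.shape[0]))
    ncols = int(header.get("ncols", arr.shape[1]))
    if arr.shape != (nrows, ncols):
        raise GridError(f"{path}: data shape {arr.shape} != header {nrows}x{ncols}")
    return arr, header


def read_pressure_raster(
    path: str | Path,
    epoch: str = "",
    cell_area_km2: float | None = None,
) -> PressureGrid:
    """Read a pressure grid, validating the 0-50 score range.

    Cell area comes from the header ``cellsize`` (interpreted as metres of an
    equal-area projection) unless overridden.
    """
    arr, header = read_ascii_raster(path)
    if "nodata_value" not in header:
        lo, hi = arr.min(), arr.max()
        if lo < 0 or hi > SCORE_MAX:
            raise GridError(f"{path}: values outside 0-{SCORE_MAX} with no declared nodata")
        nodata = DEFAULT_NODATA
    else:
        nodata = int(header["nodata_value"])
    cellsize = header.get("cellsize")
    if cell_area_km2 is None:
        if cellsize is None:
            raise GridError(f"{path}: no cellsize header and no cell area supplied")
        cell_area_km2 = (cellsize / 1000.0) ** 2
    return PressureGrid(
        arr.astype(np.int16),
        cell_area_km2=cell_area_km2,
        epoch=epoch,
        nodata_value=nodata,
        xll=header.get("xllcorner", 0.0),
        yll=header.get("yllcorner", 0.0),
        cellsize_m=cellsize,
    )


def write_realm_raster(realms: RealmMap, path: str | Path,
                       cellsize_m: float = 1000.0) -> Path:
    path = Path(path)
    nrows, ncols = realms.shape
    with path.open("w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cellsize_m}\n")
        fh.write("NODATA_value 0\n")
        np.savetxt(fh, realms.realm_ids, fmt="%d")
    return path


def read_realm_raster(path: str | Path) -> RealmMap:
    arr, header = read_ascii_raster(path)
    nodata = int(header.get("nodata_value", 0))
    ids = arr.copy()
    ids[arr == nodata] = 0
    return RealmMap(ids.astype(np.int32))


# ---------------------------------------------------------------- vectors

def _block_geometry(block: Block, grid: PressureGrid):
    side_km = grid.cellsize_m / 1000.0 if grid.cellsize_m else float(
        np.sqrt(np.asarray(grid.cell_area_km2, dtype=float))
    )
    nrows = grid.shape[0]
    boxes = [
        box(
            grid.xll + c * side_km,
            grid.yll + (nrows - r - 1) * side_km,
            grid.xll + (c + 1) * side_km,
            grid.yll + (nrows - r) * side_km,
        )
        for r, c in block.cells
    ]
    return unary_union(boxes)


def write_block_polygons(
    blocks: list[Block],
    grid: PressureGrid,
    path: str | Path,
    variant: str = "",
) -> Path:
    """Write blocks as a GeoJSON FeatureCollection of dissolved cell squares."""
    path = Path(path)
    features = []
    for b in blocks:
        geom = _block_geometry(b, grid)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "block_id": b.block_id,
                    "area_km2": b.area_km2,
                    "realm_id": b.realm_id,
                    "epoch": b.epoch,
                    "variant": variant,
                },
            }
        )
    with path.open("w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path


def read_block_polygons(path: str | Path) -> pd.DataFrame:
    """Read a block GeoJSON back as an attribute table (+ geometry area)."""
    with Path(path).open() as fh:
        fc = json.load(fh)
    rows = []
    for feat in fc["features"]:
        props = dict(feat["properties"])
        props["geometry_area"] = shapely_shape(feat["geometry"]).area
        rows.append(props)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- tables

def write_plots_csv(plots: list[ValidationPlot], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "row": [p.row for p in plots],
            "col": [p.col for p in plots],
            "visual_score_norm": [p.visual_score_norm for p in plots],
            "certain": [int(p.certain) for p in plots],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_plots_csv(path: str | Path) -> list[ValidationPlot]:
    df = pd.read_csv(path)
    required = {"plot_id", "row", "col", "visual_score_norm", "certain"}
    missing = required - set(df.columns)
    if missing:
        raise GridError(f"{path}: missing plot columns {sorted(missing)}")
    return [
        ValidationPlot(
            plot_id=rec.plot_id,
            row=int(rec.row),
            col=int(rec.col),
            visual_score_norm=float(rec.visual_score_norm),
            certain=bool(rec.certain),
        )
        for rec in df.itertuples()
    ]


def write_thresholds_csv(table: ThresholdTable, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "realm_id": rid,
            "threshold": e.threshold,
            "realm_area_km2": e.realm_area_km2,
            "captured_area_km2": e.captured_area_km2,
            "baseline_epoch": table.baseline_epoch,
            "fraction": table.fraction,
        }
        for rid, e in sorted(table.entries.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_thresholds_csv(path: str | Path) -> ThresholdTable:
    df = pd.read_csv(path)
    entries = {
        int(rec.realm_id): ThresholdEntry(
            threshold=int(rec.threshold),
            realm_area_km2=float(rec.realm_area_km2),
            captured_area_km2=float(rec.captured_area_km2),
        )
        for rec in df.itertuples()
    }
    return ThresholdTable(
        baseline_epoch=str(df["baseline_epoch"].iloc[0]),
        fraction=float(df["fraction"].iloc[0]),
        entries=entries,
    )


def write_block_inventory(blocks: list[Block], path: str | Path,
                          variant: str = "") -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "block_id": [b.block_id for b in blocks],
            "n_cells": [b.n_cells for b in blocks],
            "area_km2": [b.area_km2 for b in blocks],
            "realm_id": [b.realm_id for b in blocks],
            "epoch": [b.epoch for b in blocks],
            "variant": variant,
        }
    ).to_csv(path, index=False)
    return path


def write_report_json(report, path: str | Path) -> Path:
    path = Path(path)
    payload = dataclasses.asdict(report)
    # JSON object keys must be strings
    if "kappa_alt" in payload:
        payload["kappa_alt"] = {str(k): v for k, v in payload["kappa_alt"].items()}
    with path.open("w") as fh:
        json.dump(payload, fh, indent=2)
    return path


# ---------------------------------------------------------------- pipeline

@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either all three raster inputs (``hfp_1993``, ``hfp_2009``, ``realms``)
    are paths to existing files, or ``sim`` provides a :class:`SimConfig`
    and the inputs are simulated (``n_plots`` plots are then generated on
    the 2009 grid unless a plot table is supplied).
    """

    out_dir: str | Path = "wildmaps_run"
    hfp_1993: str | Path | None = None
    hfp_2009: str | Path | None = None
    realms: str | Path | None = None
    plots: str | Path | None = None
    sim: SimConfig | None = None
    n_plots: int = 500
    min_area_km2: float = MIN_BLOCK_AREA_KM2
    fraction: float = LOW_FRACTION
    top_k: int = LOW_TOP_K
    connectivity: int = DEFAULT_CONNECTIVITY
    tolerance: float = AGREEMENT_TOLERANCE
    seed: int = 0
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full mapping workflow and return the manifest.

    Stages: load-or-simulate inputs -> pressure-free maps (1993 and
    2009-comparable) -> per-realm thresholds -> three Last of the Wild maps
    -> plot validation.  All outputs plus a hashed manifest are written to
    ``config.out_dir``; identical config and seed yield identical outputs.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "min_area_km2": config.min_area_km2,
            "fraction": config.fraction,
            "top_k": config.top_k,
            "connectivity": config.connectivity,
            "tolerance": config.tolerance,
        },
        "inputs": {},
        "outputs": {},
        "counts": {},
    }

    # -- stage: inputs
    try:
        if config.hfp_1993 and config.hfp_2009:
            g93 = read_pressure_raster(config.hfp_1993, epoch="1993")
            g09 = read_pressure_raster(config.hfp_2009, epoch="2009")
            if config.realms is None:
                raise GridError("realm raster required when loading rasters")
            realms = read_realm_raster(config.realms)
            manifest["inputs"] = {
                "hfp_1993": str(config.hfp_1993),
                "hfp_2009": str(config.hfp_2009),
                "realms": str(config.realms),
            }
            plots = read_plots_csv(config.plots) if config.plots else []
        else:
            sim = config.sim or SimConfig(seed=config.seed)
            sim = sim.with_seed(config.seed if config.sim is None else sim.seed)
            g93, g09 = generate_grid_pair(sim)
            realms = generate_realm_partition(sim, grid=g93)
            plots = generate_validation_plots(g09, sim, config.n_plots)
            manifest["inputs"] = {"simulated": dataclasses.asdict(sim)}
        logger.info("stage=inputs land_cells=%d realms=%d plots=%d",
                    g93.n_land, len(realms.realms()), len(plots))
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    outputs: dict[str, Path] = {}

    # -- stage: pressure-free maps
    try:
        pf93 = map_pressure_free(
            g93, config.connectivity, config.min_area_km2, variant="1993"
        )
        pf09 = map_pressure_free_comparable(
            g93, g09, config.connectivity, config.min_area_km2
        )
        outputs["Pressure_free_lands_93"] = write_block_polygons(
            pf93.blocks, g93, out / "Pressure_free_lands_93.geojson", "1993"
        )
        outputs["Pressure_free_lands_09"] = write_block_polygons(
            pf09.blocks, g09, out / "Pressure_free_lands_09.geojson", "2009_comparable"
        )
        write_block_inventory(pf93.blocks, out / "Pressure_free_lands_93_blocks.csv", "1993")
        write_block_inventory(pf09.blocks, out / "Pressure_free_lands_09_blocks.csv", "2009_comparable")
        manifest["counts"]["pressure_free_blocks_1993"] = pf93.n_blocks
        manifest["counts"]["pressure_free_blocks_2009"] = pf09.n_blocks
        logger.info("stage=pressure_free blocks93=%d blocks09=%d",
                    pf93.n_blocks, pf09.n_blocks)
    except Exception as exc:
        raise RuntimeError(f"stage 'pressure_free' failed: {exc}") from exc

    # -- stage: Last of the Wild
    try:
        suite = build_low_suite(
            g93, g09, realms,
            fraction=config.fraction,
            top_k=config.top_k,
            min_area_km2=config.min_area_km2,
            connectivity=config.connectivity,
        )
        grids = {"LoW_1993": g93, "LoW_2009_comparable": g09, "LoW_2009_current": g09}
        for name, low_map in suite.maps().items():
            outputs[name] = write_block_polygons(
                low_map.blocks, grids[name], out / f"{name}.geojson", name
            )
            write_block_inventory(low_map.blocks, out / f"{name}_blocks.csv", name)
            manifest["counts"][f"{name}_blocks"] = low_map.n_blocks
        write_thresholds_csv(suite.thresholds_1993, out / "thresholds_1993.csv")
        write_thresholds_csv(suite.thresholds_2009, out / "thresholds_2009.csv")
        logger.info("stage=last_of_wild blocks=%s",
                    {k: m.n_blocks for k, m in suite.maps().items()})
    except Exception as exc:
        raise RuntimeError(f"stage 'last_of_wild' failed: {exc}") from exc

    # -- stage: validation
    if plots:
        try:
            certain = filter_certain(plots)
            overlaid = overlay_hfp(certain, g09)
            agreement = score_agreement(overlaid, tolerance=config.tolerance)
            pf_report = validate_wilderness_map(pf09, certain, config.tolerance)
            low_report = validate_low_map(suite.low_2009_current, certain, config.tolerance)
            write_report_json(agreement, out / "agreement_report.json")
            write_report_json(pf_report, out / "pressure_free_validation.json")
            write_report_json(low_report, out / "low_validation.json")
            manifest["validation"] = {
                "n_certain": len(certain),
                "rmse": agreement.rmse,
                "kappa": agreement.kappa,
                "pct_within": agreement.pct_within,
                "pressure_free_pct_agree": pf_report.pct_agree,
                "low_pct_agree": low_report.pct_agree,
            }
            logger.info("stage=validation n=%d rmse=%.4f kappa=%s",
                        agreement.n, agreement.rmse, agreement.kappa)
        except Exception as exc:
            raise RuntimeError(f"stage 'validation' failed: {exc}") from exc

    for name, path in outputs.items():
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}
    for extra in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if extra.name == "manifest.json":
            continue
        if extra.stem not in manifest["outputs"]:
            manifest["outputs"][extra.stem] = {
                "path": str(extra), "sha256": _sha256(extra)
            }
    manifest["map_products"] = [s for s in MAP_PRODUCT_STEMS if s in outputs]
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("stage=done products=%d", len(manifest["map_products"]))
    return manifest
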