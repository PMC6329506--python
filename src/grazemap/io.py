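"""Readers and writers for the pipeline's on-disk formats.

Rasters are stored as ESRI ASCII grids (``.asc``): a six-line header
(ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value) followed by rows of
whitespace-separated values, north row first — a plain-text format readable by
every GIS.  Settlements travel as GeoJSON point features, statistics as CSV,
configuration as YAML, and run manifests as JSON with SHA-256 content hashes.
All coordinates are projected metres; energies are MJ in every file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .grid import Grid

NODATA = -9999.0


def write_ascii_grid(path, grid: Grid, values: np.ndarray, fmt: str = "%.10g") -> None:
    """Write one raster band as an ESRI ASCII grid; NaN becomes the nodata value."""
    v = np.asarray(values, dtype=float)
    if v.shape != grid.shape:
        raise ValidationError("raster shape does not match grid")
    v = np.where(np.isfinite(v), v, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {grid.y_origin - grid.n_rows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, v, fmt=fmt)


def read_ascii_grid(path, crs_label: str = "local-metric") -> tuple[Grid, np.ndarray]:
    """Read an ESRI ASCII grid; nodata values come back as NaN."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(n_rows, n_cols)
    cell = header["cellsize"]
    grid = Grid(
        n_rows,
        n_cols,
        cell,
        header["xllcorner"],
        header["yllcorner"] + n_rows * cell,
        crs_label,
    )
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    return grid, values


def write_settlements_geojson(path, settlements: pd.DataFrame) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(s.x), float(s.y)]},
            "properties": {
                "settlement_id": int(s.settlement_id),
                "population": int(s.population),
                "district_id": int(s.district_id),
            },
        }
        for s in settlements.itertuples()
    ]
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_settlements_geojson(path) -> pd.DataFrame:
    doc = json.loads(Path(path).read_text())
    rows = []
    for f in doc["features"]:
        x, y = f["geometry"]["coordinates"]
        rows.append({"x": float(x), "y": float(y), **f["properties"]})
    df = pd.DataFrame(rows)
    return df[["settlement_id", "x", "y", "population", "district_id"]]


def write_yaml(path, payload: dict) -> None:
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, artifacts: dict[str, str | Path], config: dict | None = None) -> dict:
    """Write a machine-readable run manifest: artifact paths + content hashes."""
    from . import __version__

    entries = {
        name: {"path": str(p), "sha256": sha256_file(p)} for name, p in sorted(artifacts.items())
    }
    doc = {"version": __version__, "artifacts": entries, "config": config or {}}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
    return doc


# ---------------------------------------------------------------------------
# whole-bundle persistence (the file layout the CLI stages exchange)

BUNDLE_FILES = {
    "npp": "npp.asc",
    "cover": "cover.asc",
    "district_raster": "districts.asc",
    "settlements": "settlements.geojson",
    "districts": "districts.csv",
    "livestock_counts": "livestock_counts.csv",
    "census": "census.csv",
    "nutritive": "nutritive.csv",
    "fodder_production": "fodder_production.csv",
    "fodder_shares": "fodder_shares.csv",
    "fodder_conversion": "fodder_conversion.csv",
    "production": "production.csv",
    "per_head": "per_head.csv",
    "config": "synth_config.yaml",
}


def save_bundle(directory, bundle) -> dict[str, Path]:
    """Write a ModelInputs bundle to a directory in the pipeline's file formats."""
    import dataclasses

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def p(key):
        paths[key] = d / BUNDLE_FILES[key]
        return paths[key]

    write_ascii_grid(p("npp"), bundle.grid, bundle.npp.values)
    write_ascii_grid(p("cover"), bundle.grid, bundle.cover.classes.astype(float), fmt="%d")
    write_ascii_grid(
        p("district_raster"), bundle.grid, bundle.district_raster.district_id.astype(float), fmt="%d"
    )
    write_settlements_geojson(p("settlements"), bundle.settlements)
    for key in (
        "districts",
        "livestock_counts",
        "census",
        "nutritive",
        "fodder_production",
        "fodder_shares",
        "fodder_conversion",
        "production",
        "per_head",
    ):
        getattr(bundle, key).to_csv(p(key), index=False)
    cfg = dataclasses.asdict(bundle.config)
    cfg["livestock_per_capita"] = {f"{sp}:{ft}": v for (sp, ft), v in cfg["livestock_per_capita"].items()}
    cfg["fodder_kg_per_capita"] = {f"{t}:{ft}": v for (t, ft), v in cfg["fodder_kg_per_capita"].items()}
    write_yaml(p("config"), cfg)
    return paths


def load_bundle(directory):
    """Read a bundle directory back into a ModelInputs."""
    from .grid import CoverRaster, DistrictRaster, NPPRaster
    from .supply import SupplyParams
    from .synthetic import ModelInputs, SynthConfig

    d = Path(directory)
    cfg_raw = read_yaml(d / BUNDLE_FILES["config"])
    cfg_raw["livestock_per_capita"] = {
        tuple(k.split(":")): v for k, v in cfg_raw["livestock_per_capita"].items()
    }
    cfg_raw["fodder_kg_per_capita"] = {
        tuple(k.split(":")): v for k, v in cfg_raw["fodder_kg_per_capita"].items()
    }
    cfg = SynthConfig(**cfg_raw)

    grid, npp_values = read_ascii_grid(d / BUNDLE_FILES["npp"])
    _, cover_values = read_ascii_grid(d / BUNDLE_FILES["cover"])
    _, district_values = read_ascii_grid(d / BUNDLE_FILES["district_raster"])
    tables = {
        key: pd.read_csv(d / BUNDLE_FILES[key])
        for key in (
            "districts",
            "livestock_counts",
            "census",
            "nutritive",
            "fodder_production",
            "fodder_shares",
            "fodder_conversion",
            "production",
            "per_head",
        )
    }
    return ModelInputs(
        config=cfg,
        grid=grid,
        npp=NPPRaster(grid, npp_values),
        cover=CoverRaster(grid, cover_values.astype(int)),
        district_raster=DistrictRaster(grid, district_values.astype(int)),
        settlements=read_settlements_geojson(d / BUNDLE_FILES["settlements"]),
        supply_params=SupplyParams(),
        **tables,
    )
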