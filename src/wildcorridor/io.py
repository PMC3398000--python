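"""Reading and writing the pipeline's file formats.

Rasters travel as single-band ESRI ASCII grids (.asc) — a plain-text
format every desktop GIS reads — with the nodata tag honoured. Vector
layers travel as GeoJSON FeatureCollections in planar-metre coordinates.
Cost tables, weight schemes and run parameters live in one YAML config.
Pellet plots and tabular reports are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .prey_survey import PelletPlot
from .raster_core import CostTable, Grid, GridSpec, VectorLayer

_GEOJSON_TYPE = {
    "Point": "point",
    "MultiPoint": "point",
    "LineString": "polyline",
    "MultiLineString": "polyline",
    "Polygon": "polygon",
    "MultiPolygon": "polygon",
}


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    spec = grid.spec
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x}\n"
        f"yllcorner {spec.origin_y - spec.n_rows * spec.cell_size}\n"
        f"cellsize {spec.cell_size}\n"
        f"NODATA_value {spec.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.asarray(grid.values, dtype=float), fmt="%.6g")


def read_ascii_grid(path: str | Path, kind: str = "continuous") -> Grid:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        nodata=header.get("nodata_value", -9999.0),
    )
    return Grid(spec, values.reshape(spec.shape), kind)


def write_geojson(layer: VectorLayer, path: str | Path) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": attrs}
        for geom, attrs in layer.features
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path: str | Path) -> VectorLayer:
    with open(path) as fh:
        collection = json.load(fh)
    feats = [
        (shape(f["geometry"]), f.get("properties") or {})
        for f in collection["features"]
    ]
    if not feats:
        raise ValueError(f"{path}: empty FeatureCollection")
    gtype = _GEOJSON_TYPE[feats[0][0].geom_type]
    return VectorLayer(gtype, feats)


def write_geometry(geom, path: str | Path, properties: dict | None = None) -> None:
    """Write a bare shapely geometry as a one-feature GeoJSON."""
    feature = {
        "type": "Feature",
        "geometry": mapping(geom),
        "properties": properties or {},
    }
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)


def cost_table_from_config(name: str, entries: list, default=None) -> CostTable:
    """Build a CostTable from [match, cost] config pairs.

    Numeric matches are two-element [lo, hi] lists; anything else is a
    category label.
    """
    parsed = []
    for match, cost in entries:
        if isinstance(match, list) and len(match) == 2:
            parsed.append(((float(match[0]), float(match[1])), int(cost)))
        else:
            parsed.append((match, int(cost)))
    return CostTable(name, parsed, default=default)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def write_plots_csv(plots: list[PelletPlot], path: str | Path) -> None:
    from .prey_survey import plots_to_frame

    plots_to_frame(plots).to_csv(path, index=False)


def read_plots_csv(path: str | Path) -> list[PelletPlot]:
    df = pd.read_csv(path)
    species = [c for c in df.columns if c not in ("transect_id", "habitat")]
    return [
        PelletPlot(
            str(row["transect_id"]),
            str(row["habitat"]),
            {sp: int(row[sp]) for sp in species},
        )
        for _, row in df.iterrows()
    ]
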