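"""Raster and table input/output.

Rasters travel as single-band ESRI ASCII grids (.asc) — a plain-text format
with a six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by row-major cell values, top row first.  Values
round-trip at full double precision; the CRS tag is not part of the format,
so readers assign the package default unless told otherwise.  Tables
(evaluation units, scores, areas, valuations) travel as CSV; unit outlines
can optionally be written as GeoJSON polygons built from merged cell
squares.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_landscape import CategoricalLayer, GridSpec, IndicatorLayer, UnitMap

DEFAULT_NODATA = -9999.0


def write_ascii_grid(layer: IndicatorLayer | CategoricalLayer, path) -> Path:
    """Write a layer as a single-band ESRI ASCII grid."""
    path = Path(path)
    grid = layer.grid
    if isinstance(layer, CategoricalLayer):
        values = layer.class_ids.astype(float)
        nodata_mask = np.zeros(grid.shape, dtype=bool)
    else:
        values = layer.values
        nodata_mask = layer.nodata_mask
    out = np.where(nodata_mask, DEFAULT_NODATA, values)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y - grid.nrows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {DEFAULT_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    return path


def read_ascii_grid(
    path,
    indicator_id: str | None = None,
    kind: str = "continuous",
    legend: dict[int, str] | None = None,
    crs_tag: str = "EPSG:32650",
) -> IndicatorLayer | CategoricalLayer:
    """Read an ESRI ASCII grid into a layer.

    ``kind="categorical"`` returns a CategoricalLayer (legend defaults to
    ``{id: str(id)}`` for the ids present); otherwise an IndicatorLayer with
    NODATA cells masked.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    cell = header["cellsize"]
    grid = GridSpec(
        nrows=nrows,
        ncols=ncols,
        cell_size=cell,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * cell,
        crs_tag=crs_tag,
    )
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    mask = data == nodata
    name = indicator_id or path.stem
    if kind == "categorical":
        ids = data.astype(np.int64)
        if legend is None:
            legend = {int(i): str(int(i)) for i in np.unique(ids)}
        return CategoricalLayer(grid, ids, legend)
    values = np.where(mask, np.nan, data)
    values[mask] = 0.0  # masked cells carry a placeholder, flagged by mask
    return IndicatorLayer(grid, name, values, mask, kind="continuous")


def require_aligned(*layers) -> GridSpec:
    """Assert that all layers share one grid; the pipeline never resamples
    silently."""
    grids = {l.grid for l in layers}
    if len(grids) != 1:
        detail = "; ".join(
            f"{getattr(l, 'indicator_id', type(l).__name__)}: "
            f"{l.grid.nrows}x{l.grid.ncols}@{l.grid.cell_size}m"
            for l in layers
        )
        raise ValueError(f"layers are not aligned on one grid ({detail})")
    return layers[0].grid


def write_unit_table(units: UnitMap, path) -> Path:
    """Write the evaluation-unit attribute table as CSV."""
    path = Path(path)
    units.units.to_csv(path, index=False)
    return path


def write_unit_labels(units: UnitMap, path) -> Path:
    """Write the unit-id label raster as an ASCII grid."""
    legend = {int(i): str(int(i)) for i in np.unique(units.labels)}
    layer = CategoricalLayer(units.grid, units.labels, legend)
    return write_ascii_grid(layer, path)


def units_to_geojson(units: UnitMap, path) -> Path:
    """Write unit outlines as a GeoJSON FeatureCollection of polygons.

    Each unit polygon is the union of its cell squares in the grid's
    projected coordinates; intended for small grids and visual inspection.
    """
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    grid = units.grid
    cs = grid.cell_size
    features = []
    for row in units.units.itertuples():
        cells = np.argwhere(units.labels == row.unit_id)
        boxes = [
            box(
                grid.origin_x + c * cs,
                grid.origin_y - (r + 1) * cs,
                grid.origin_x + (c + 1) * cs,
                grid.origin_y - r * cs,
            )
            for r, c in cells
        ]
        geom = unary_union(boxes)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "unit_id": int(row.unit_id),
                    "region_id": int(row.region_id),
                    "soil_id": int(row.soil_id),
                    "landuse_id": int(row.landuse_id),
                    "area_hm2": float(row.area_hm2),
                },
            }
        )
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path


def read_matrix_csv(path) -> tuple[np.ndarray, list[str]]:
    """Read a judgment matrix from CSV (square, first column = row ids)."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]
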