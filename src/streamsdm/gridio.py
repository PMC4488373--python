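"""Plain-text geospatial I/O.

Rasters are read and written as ESRI ASCII grids (.asc) — a simple,
widely supported text format (header of ncols/nrows/corner/cellsize
followed by whitespace-separated values, row 0 = north). Vector layers
travel as GeoJSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import shape, mapping

from streamsdm.units import StreamNetwork

NODATA = -9999.0


def write_ascii_grid(path: str | Path, grid: np.ndarray, cell_m: float,
                     xllcorner: float = 0.0, yllcorner: float = 0.0) -> None:
    grid = np.asarray(grid, dtype=float)
    header = (f"ncols {grid.shape[1]}\nnrows {grid.shape[0]}\n"
              f"xllcorner {xllcorner}\nyllcorner {yllcorner}\n"
              f"cellsize {cell_m}\nNODATA_value {NODATA}\n")
    body = np.where(np.isfinite(grid), grid, NODATA)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    grid = np.loadtxt(lines[n_header:])
    grid = np.atleast_2d(grid)
    nodata = meta.get("nodata_value", NODATA)
    grid = np.where(grid == nodata, np.nan, grid)
    return grid, meta


def write_streams_geojson(path: str | Path, net: StreamNetwork) -> None:
    with open(path, "w") as fh:
        json.dump(net.to_geojson(), fh)


def read_streams_geojson(path: str | Path) -> StreamNetwork:
    with open(path) as fh:
        return StreamNetwork.from_geojson(json.load(fh))


def read_polygons_geojson(path: str | Path) -> list:
    with open(path) as fh:
        obj = json.load(fh)
    polys = []
    for feat in obj.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type == "MultiPolygon":
            polys.extend(geom.geoms)
        else:
            polys.append(geom)
    return polys


def write_polygons_geojson(path: str | Path, polygons: list) -> None:
    obj = {
        "type": "FeatureCollection",
        "features": [{"type": "Feature", "properties": {}, "geometry": mapping(p)}
                     for p in polygons],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)
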