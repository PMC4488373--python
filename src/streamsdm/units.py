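"""Stream-constrained sample-unit lattice.

The analysis operates on square sample units (default 200 m) laid out
on a regular grid; only units whose cell intersects the retained stream
network are kept, and units majority-covered by mapped water bodies are
masked out. All downstream stages key off the unit ids of this lattice.

Grid convention: planar projected coordinates in meters; the grid is
row-major and 0-based with its origin at the upper-left corner, so cell
``(r, c)`` spans ``[x0 + c*s, x0 + (c+1)*s)`` in x and
``(y0 - (r+1)*s, y0 - r*s]`` in y (half-open; ``s`` = cell size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box
from shapely.ops import unary_union
from shapely.strtree import STRtree

log = logging.getLogger(__name__)


@dataclass
class StreamNetwork:
    """Vector stream network: polyline segments with optional stream order."""

    segments: list[LineString]
    order: list[int | None] | None = None

    def __post_init__(self) -> None:
        for seg in self.segments:
            coords = np.asarray(seg.coords)
            if len(coords) < 2:
                raise ValueError("stream segments need at least 2 vertices")
            if not np.all(np.isfinite(coords)):
                raise ValueError("stream segment has non-finite coordinates")
        if self.order is not None and len(self.order) != len(self.segments):
            raise ValueError("order list length must match segment count")

    def __len__(self) -> int:
        return len(self.segments)

    def union(self):
        """Merged geometry of all segments (empty geometry if none)."""
        return unary_union(self.segments) if self.segments else LineString()

    @classmethod
    def from_geojson(cls, obj: dict) -> "StreamNetwork":
        segs, orders = [], []
        for feat in obj.get("features", []):
            geom = feat["geometry"]
            props = feat.get("properties") or {}
            lines = [geom["coordinates"]] if geom["type"] == "LineString" else geom["coordinates"]
            for coords in lines:
                segs.append(LineString(coords))
                orders.append(props.get("order"))
        has_order = any(o is not None for o in orders)
        return cls(segs, orders if has_order else None)

    def to_geojson(self) -> dict:
        feats = []
        for i, seg in enumerate(self.segments):
            props = {}
            if self.order is not None and self.order[i] is not None:
                props["order"] = int(self.order[i])
            feats.append(
                {
                    "type": "Feature",
                    "properties": props,
                    "geometry": {"type": "LineString", "coordinates": [list(xy) for xy in seg.coords]},
                }
            )
        return {"type": "FeatureCollection", "features": feats}


@dataclass
class SampleUnitGrid:
    """The stream-constrained analysis lattice.

    ``unit_ids`` holds the retained ``(row, col)`` cells; ``water_mask``
    the cells that were removed as water.
    """

    origin: tuple[float, float]
    cell_m: float
    nrows: int
    ncols: int
    unit_ids: set[tuple[int, int]]
    water_mask: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for r, c in self.unit_ids:
            if not (0 <= r < self.nrows and 0 <= c < self.ncols):
                raise ValueError(f"unit {(r, c)} outside grid bounds")
        if self.unit_ids & self.water_mask:
            raise ValueError("unit_ids and water_mask overlap")

    # ---- id helpers -------------------------------------------------
    def uid(self, rc: tuple[int, int]) -> int:
        """Flat integer id of cell (row, col)."""
        r, c = rc
        return r * self.ncols + c

    def rc(self, uid: int) -> tuple[int, int]:
        return divmod(int(uid), self.ncols)

    @property
    def uids(self) -> list[int]:
        """Sorted flat ids of retained units."""
        return sorted(self.uid(rc) for rc in self.unit_ids)

    # ---- geometry helpers -------------------------------------------
    def cell_box(self, rc: tuple[int, int]):
        r, c = rc
        x0, y0 = self.origin
        s = self.cell_m
        return box(x0 + c * s, y0 - (r + 1) * s, x0 + (c + 1) * s, y0 - r * s)

    def center(self, rc: tuple[int, int]) -> tuple[float, float]:
        r, c = rc
        x0, y0 = self.origin
        s = self.cell_m
        return (x0 + (c + 0.5) * s, y0 - (r + 0.5) * s)

    def centers(self, uids: list[int]) -> np.ndarray:
        return np.array([self.center(self.rc(u)) for u in uids])

    def contains_xy(self, x: float, y: float) -> tuple[int, int] | None:
        """Cell (row, col) containing a point under the half-open rule."""
        x0, y0 = self.origin
        s = self.cell_m
        c = int(np.floor((x - x0) / s))
        r = int(np.ceil((y0 - y) / s)) - 1
        if r == -1 and y == y0:  # top edge belongs to row 0
            r = 0
        if 0 <= r < self.nrows and 0 <= c < self.ncols:
            return (r, c)
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rc in sorted(self.unit_ids):
            x, y = self.center(rc)
            rows.append({"unit_id": self.uid(rc), "row": rc[0], "col": rc[1], "x": x, "y": y})
        return pd.DataFrame(rows)


def filter_streams(fine: StreamNetwork, ordered: StreamNetwork, buffer_m: float = 50.0,
                   min_order: int | None = None) -> StreamNetwork:
    """Keep fine-scale segments lying within ``buffer_m`` of the ordered network.

    Emulates discarding unordered headwater fragments: a fine segment is
    retained when any part of it comes within ``buffer_m`` of any segment
    of the coarser, order-bearing network (optionally restricted to
    ``order >= min_order``). The buffer absorbs positional mismatch
    between the two datasets.
    """
    if buffer_m < 0:
        raise ValueError("buffer_m must be >= 0")
    ordered_segs = ordered.segments
    if min_order is not None:
        if ordered.order is None:
            raise ValueError("min_order given but ordered network has no order attribute")
        ordered_segs = [s for s, o in zip(ordered.segments, ordered.order)
                        if o is not None and o >= min_order]
    if not fine.segments or not ordered_segs:
        return StreamNetwork([], [] if fine.order is not None else None)
    tree = STRtree(ordered_segs)
    keep = []
    for i, seg in enumerate(fine.segments):
        minx, miny, maxx, maxy = seg.bounds
        env = box(minx - buffer_m, miny - buffer_m, maxx + buffer_m, maxy + buffer_m)
        cand = tree.query(env)
        hit = any(ordered_segs[j].distance(seg) <= buffer_m for j in cand)
        if hit:
            keep.append(i)
    return StreamNetwork(
        [fine.segments[i] for i in keep],
        [fine.order[i] for i in keep] if fine.order is not None else None,
    )


def build_units(streams: StreamNetwork, origin: tuple[float, float], cell_m: float = 200.0,
                nrows: int = 0, ncols: int = 0) -> SampleUnitGrid:
    """Rasterize the stream network to the set of intersected cells.

    A cell is a unit iff its (closed) square intersects any stream
    polyline — exact segment/box intersection, so long segments crossing
    a cell with no vertex inside it still register. Stream parts outside
    the grid are ignored with a log message.
    """
    if cell_m <= 0:
        raise ValueError("cell_m must be positive")
    if nrows <= 0 or ncols <= 0:
        raise ValueError("grid dimensions must be positive")
    x0, y0 = origin
    units: set[tuple[int, int]] = set()
    clipped_any = False
    for seg in streams.segments:
        minx, miny, maxx, maxy = seg.bounds
        c0 = int(np.floor((minx - x0) / cell_m))
        c1 = int(np.floor((maxx - x0) / cell_m))
        r0 = int(np.floor((y0 - maxy) / cell_m))
        r1 = int(np.floor((y0 - miny) / cell_m))
        if c0 < 0 or r0 < 0 or c1 >= ncols or r1 >= nrows:
            clipped_any = True
        for r in range(max(r0, 0), min(r1, nrows - 1) + 1):
            for c in range(max(c0, 0), min(c1, ncols - 1) + 1):
                if (r, c) in units:
                    continue
                cell = box(x0 + c * cell_m, y0 - (r + 1) * cell_m,
                           x0 + (c + 1) * cell_m, y0 - r * cell_m)
                # positive-length clip required: a bare corner touch does
                # not make a cell a stream unit
                if seg.intersection(cell).length > 0:
                    units.add((r, c))
    if clipped_any:
        log.warning("stream parts outside the grid bounds were ignored")
    return SampleUnitGrid((x0, y0), cell_m, nrows, ncols, units)


def mask_water(grid: SampleUnitGrid, water: list) -> SampleUnitGrid:
    """Remove units majority-covered (>50% area) by water polygons."""
    for poly in water:
        if not poly.is_valid:
            raise ValueError("invalid (self-intersecting) water polygon")
    if not water:
        return grid
    water_union = unary_union(water)
    keep: set[tuple[int, int]] = set()
    removed = set(grid.water_mask)
    cell_area = grid.cell_m**2
    for rc in grid.unit_ids:
        cell = grid.cell_box(rc)
        frac = cell.intersection(water_union).area / cell_area
        if frac > 0.5:
            removed.add(rc)
        else:
            keep.add(rc)
    return SampleUnitGrid(grid.origin, grid.cell_m, grid.nrows, grid.ncols, keep, removed)
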