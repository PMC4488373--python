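"""Per-unit feature assembly and PCA reduction.

Pixel-resolution layers (and polygon attribute layers) are aggregated
to the sample-unit lattice with per-layer rules — majority for coarse
categorical-resolution climate surfaces, area-weighted means for soil
polygons, min/max/median/variance for the terrain and spectral layers —
and per-unit stream slope is computed from the DEM and the stream
polylines. The resulting variable table is then reduced by a PCA on the
correlation matrix, retaining components with eigenvalue > 1 (Kaiser's
rule, strict inequality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.strtree import STRtree

from streamsdm.units import SampleUnitGrid, StreamNetwork

log = logging.getLogger(__name__)

#: FeatureTable: a pandas DataFrame indexed by integer unit_id, one
#: named column per environmental variable, no missing values.
FeatureTable = pd.DataFrame

RULES = {"majority", "area_weighted_mean", "min", "max", "median", "variance"}


def _pixel_unit_index(grid: SampleUnitGrid, layer_shape: tuple[int, int],
                      px_m: float, origin: tuple[float, float]) -> np.ndarray:
    """Flat unit id per pixel (-1 where the pixel center falls in no unit)."""
    nr, nc = layer_shape
    x0, y0 = origin
    xs = x0 + (np.arange(nc) + 0.5) * px_m
    ys = y0 - (np.arange(nr) + 0.5) * px_m
    cols = np.floor((xs - grid.origin[0]) / grid.cell_m).astype(int)
    rows = np.floor((grid.origin[1] - ys) / grid.cell_m).astype(int)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    uid = rr * grid.ncols + cc
    in_grid = (rr >= 0) & (rr < grid.nrows) & (cc >= 0) & (cc < grid.ncols)
    uid[~in_grid] = -1
    unit_uids = set(grid.uids)
    flat = uid.ravel()
    keep = np.isin(flat, list(unit_uids))
    flat = np.where(keep, flat, -1)
    return flat.reshape(layer_shape)


def _aggregate_pixels(values: np.ndarray, uid_map: np.ndarray, rule: str) -> pd.Series:
    mask = uid_map >= 0
    s = pd.Series(values[mask].ravel())
    g = s.groupby(uid_map[mask].ravel())
    if rule == "majority":
        # majority value among pixels; ties broken toward the smallest value
        return g.agg(lambda v: v.value_counts().sort_index().idxmax())
    if rule == "area_weighted_mean":  # equal-area pixels: plain mean
        return g.mean()
    if rule == "min":
        return g.min()
    if rule == "max":
        return g.max()
    if rule == "median":
        return g.median()
    if rule == "variance":
        return g.var(ddof=1).fillna(0.0)
    raise ValueError(f"unknown aggregation rule: {rule}")


def _aggregate_polygons(grid: SampleUnitGrid, polygons: list, values: list[float]) -> pd.Series:
    """Area-weighted mean of polygon attribute values per unit."""
    tree = STRtree(polygons)
    out = {}
    for rc in grid.unit_ids:
        cell = grid.cell_box(rc)
        num = den = 0.0
        for j in tree.query(cell):
            a = polygons[j].intersection(cell).area
            if a > 0:
                num += a * values[j]
                den += a
        if den > 0:
            out[grid.uid(rc)] = num / den
    return pd.Series(out)


def aggregate_layers(grid: SampleUnitGrid, layers: dict, rules: dict[str, str],
                     px_m: float | None = None, origin: tuple[float, float] | None = None) -> FeatureTable:
    """Aggregate named layers to the unit lattice using per-layer rules.

    ``layers`` maps a variable name either to a 2-D pixel array
    (georegistered to the grid: pixel size ``px_m``, shared ``origin``,
    defaulting to the grid's own origin) or, for the
    ``area_weighted_mean`` rule, optionally to a ``(polygons, values)``
    pair. Units left with no valid pixels for some layer are dropped and
    logged.
    """
    origin = grid.origin if origin is None else origin
    cols = {}
    for name, layer in layers.items():
        rule = rules[name]
        if rule not in RULES:
            raise ValueError(f"unknown aggregation rule {rule!r} for layer {name!r}")
        if isinstance(layer, tuple):
            if rule != "area_weighted_mean":
                raise ValueError("polygon layers support only area_weighted_mean")
            cols[name] = _aggregate_polygons(grid, layer[0], layer[1])
        else:
            arr = np.asarray(layer, dtype=float)
            if px_m is None:
                raise ValueError("px_m required for pixel layers")
            uid_map = _pixel_unit_index(grid, arr.shape, px_m, origin)
            cols[name] = _aggregate_pixels(arr, uid_map, rule)
    table = pd.DataFrame(cols).reindex(sorted(grid.uids))
    dropped = table.index[table.isna().any(axis=1)]
    if len(dropped):
        log.warning("dropping %d units with missing data: %s", len(dropped), list(dropped[:20]))
        table = table.drop(index=dropped)
    table.index.name = "unit_id"
    return table


def stream_slope(grid: SampleUnitGrid, dem: np.ndarray, streams: StreamNetwork,
                 px_m: float, origin: tuple[float, float] | None = None,
                 sample_step_m: float | None = None) -> pd.Series:
    """Per-unit percent stream slope.

    100 x (max - min elevation among stream-crossed DEM pixels in the
    unit) / (stream length within the unit). Pixels crossed by the
    stream are found by sampling each in-unit stream portion at
    sub-pixel spacing.
    """
    origin = grid.origin if origin is None else origin
    step = px_m / 2.0 if sample_step_m is None else sample_step_m
    x0, y0 = origin
    nr, nc = dem.shape
    out = {}
    segs = streams.segments
    tree = STRtree(segs) if segs else None
    for rc in sorted(grid.unit_ids):
        cell = grid.cell_box(rc)
        length = 0.0
        zmin, zmax = np.inf, -np.inf
        if tree is not None:
            for j in tree.query(cell):
                clipped = segs[j].intersection(cell)
                if clipped.is_empty or clipped.length == 0:
                    continue
                length += clipped.length
                parts = getattr(clipped, "geoms", [clipped])
                for part in parts:
                    if part.length == 0:
                        continue
                    n = max(int(np.ceil(part.length / step)) + 1, 2)
                    for t in np.linspace(0, part.length, n):
                        p = part.interpolate(t)
                        pc = int((p.x - x0) // px_m)
                        pr = int((y0 - p.y) // px_m)
                        if 0 <= pr < nr and 0 <= pc < nc:
                            z = dem[pr, pc]
                            zmin, zmax = min(zmin, z), max(zmax, z)
        if length > 0 and np.isfinite(zmin):
            out[grid.uid(rc)] = 100.0 * (zmax - zmin) / length
        else:  # guarded: unit listed without stream length
            out[grid.uid(rc)] = 0.0
    s = pd.Series(out)
    s.index.name = "unit_id"
    return s


@dataclass
class PCATransform:
    """Correlation-matrix PCA with Kaiser retention.

    ``loadings`` columns are unit-norm eigenvectors ordered by
    descending eigenvalue; the sign of each is fixed so its
    largest-magnitude loading is positive (eigenvector signs are
    otherwise arbitrary and would not reproduce across runs).
    """

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (p, p)
    eigenvalues: np.ndarray  # descending
    retained: int

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "retained": int(self.retained),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCATransform":
        return cls(d["columns"], np.array(d["means"]), np.array(d["sds"]),
                   np.array(d["loadings"]), np.array(d["eigenvalues"]), int(d["retained"]))


def pca_fit(table: FeatureTable) -> PCATransform:
    """Fit a PCA on the correlation matrix of the feature table."""
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need at least 2 columns and 3 rows")
    means = table.mean(axis=0).to_numpy()
    sds = table.std(axis=0, ddof=1).to_numpy()
    scale = np.maximum(np.abs(means), 1.0)
    constant = [c for c, s, sc in zip(table.columns, sds, scale)
                if not np.isfinite(s) or s <= 1e-12 * sc]
    if constant:
        raise ValueError(f"constant column(s) cannot be standardized: {constant}")
    z = (table.to_numpy() - means) / sds
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    for j in range(eigvec.shape[1]):  # fix sign: largest-|loading| positive
        k = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    retained = int(np.sum(eigval > 1.0))
    return PCATransform(list(table.columns), means, sds, eigvec, eigval, retained)


def pca_transform(table: FeatureTable, transform: PCATransform) -> FeatureTable:
    """Project a feature table onto the retained components (PC1..PCm)."""
    missing = [c for c in transform.columns if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    z = (table[transform.columns].to_numpy() - transform.means) / transform.sds
    m = max(transform.retained, 1)
    scores = z @ transform.loadings[:, :m]
    out = pd.DataFrame(scores, index=table.index, columns=[f"PC{j + 1}" for j in range(m)])
    out.index.name = "unit_id"
    return out
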