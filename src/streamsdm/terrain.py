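"""Geomorphometric predictors derived from a DEM.

Implements the terrain layers used by the habitat models: sink filling
(priority-flood with an epsilon gradient), percent slope, the vector
ruggedness measure (VRM) at two window sizes, a multiresolution index
of valley-bottom flatness (MRVBF), and D8 flow accumulation (catchment
area). All operate on 2-D numpy elevation grids in meters with square
cells.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

# D8 neighbor offsets in the fixed tie-break order E, SE, S, SW, W, NW, N, NE
_D8 = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_D8_DIST = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2)])


@dataclass
class TerrainStack:
    """Bundle of terrain-derived grids at DEM resolution."""

    filled_dem: np.ndarray
    slope_pct: np.ndarray
    vrm3: np.ndarray
    vrm18: np.ndarray
    mrvbf: np.ndarray
    catch_area: np.ndarray


def fill_sinks(dem: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Raise closed depressions so every cell drains to the grid edge.

    Priority-flood: cells are flooded inward from the boundary in
    increasing elevation order; any cell lower than the spill level of
    its processed neighbor is raised to that level plus ``epsilon``,
    which also tilts flats so downstream routing never stalls.
    """
    dem = np.asarray(dem, dtype=float)
    if dem.ndim != 2:
        raise ValueError("dem must be 2-D")
    if not np.any(np.isfinite(dem)):
        raise ValueError("dem is all-NaN")
    nr, nc = dem.shape
    out = np.full_like(dem, np.inf)
    closed = np.zeros(dem.shape, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for r in range(nr):
        for c in (0, nc - 1):
            heapq.heappush(heap, (dem[r, c], r, c))
            closed[r, c] = True
    for c in range(1, nc - 1):
        for r in (0, nr - 1):
            heapq.heappush(heap, (dem[r, c], r, c))
            closed[r, c] = True
    while heap:
        z, r, c = heapq.heappop(heap)
        out[r, c] = z
        for dr, dc in _D8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not closed[rr, cc]:
                closed[rr, cc] = True
                heapq.heappush(heap, (max(dem[rr, cc], z + epsilon), rr, cc))
    return out


def slope_percent(dem: np.ndarray, cell_m: float) -> np.ndarray:
    """Percent slope, 100*||grad z||, central differences (one-sided at edges)."""
    if cell_m <= 0:
        raise ValueError("cell_m must be positive")
    dem = np.asarray(dem, dtype=float)
    gy, gx = np.gradient(dem, cell_m)
    return 100.0 * np.hypot(gx, gy)


def vrm(dem: np.ndarray, cell_m: float, window: int) -> np.ndarray:
    """Vector ruggedness measure: dispersion of unit surface normals.

    Per cell, ``1 - |sum of unit normals| / n`` over a ``window`` x
    ``window`` neighborhood (Sappington's method). 0 on planes — even
    steep ones — and approaches 1 where normals point every which way.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    dem = np.asarray(dem, dtype=float)
    if window > min(dem.shape):
        raise ValueError("window larger than grid")
    gy, gx = np.gradient(dem, cell_m)
    # unit normal of the local tangent plane
    norm = np.sqrt(1.0 + gx**2 + gy**2)
    nx, ny, nz = -gx / norm, -gy / norm, 1.0 / norm
    n = window * window
    sx = ndimage.uniform_filter(nx, size=window, mode="nearest") * n
    sy = ndimage.uniform_filter(ny, size=window, mode="nearest") * n
    sz = ndimage.uniform_filter(nz, size=window, mode="nearest") * n
    resultant = np.sqrt(sx**2 + sy**2 + sz**2)
    return np.clip(1.0 - resultant / n, 0.0, 1.0)


def d8_directions(filled_dem: np.ndarray) -> np.ndarray:
    """Steepest-descent D8 direction index (0-7, order E,SE,S,SW,W,NW,N,NE).

    -1 marks outlets (no lower neighbor; flow leaves the grid). Ties are
    broken by the fixed neighbor order so routing is deterministic.
    """
    z = np.asarray(filled_dem, dtype=float)
    nr, nc = z.shape
    direction = np.full(z.shape, -1, dtype=int)
    for r in range(nr):
        for c in range(nc):
            best, best_k = 0.0, -1
            for k, (dr, dc) in enumerate(_D8):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc:
                    drop = (z[r, c] - z[rr, cc]) / _D8_DIST[k]
                    if drop > best:  # strict: ties keep the earlier neighbor
                        best, best_k = drop, k
            direction[r, c] = best_k
    return direction


def flow_accumulation_d8(filled_dem: np.ndarray, cell_m: float) -> np.ndarray:
    """D8 catchment area (m^2), each cell contributing its own area.

    The DEM must be sink-filled (with epsilon flats removal) so every
    non-outlet cell has a strictly lower neighbor.
    """
    if cell_m <= 0:
        raise ValueError("cell_m must be positive")
    z = np.asarray(filled_dem, dtype=float)
    nr, nc = z.shape
    direction = d8_directions(z)
    interior_stuck = (direction == -1)
    interior_stuck[0, :] = interior_stuck[-1, :] = False
    interior_stuck[:, 0] = interior_stuck[:, -1] = False
    if np.any(interior_stuck):
        raise ValueError("unresolvable flat: interior cell with no downslope neighbor "
                         "(run fill_sinks first)")
    area = np.full(z.shape, cell_m**2, dtype=float)
    order = np.argsort(z, axis=None)[::-1]  # high to low
    for idx in order:
        r, c = divmod(int(idx), nc)
        k = direction[r, c]
        if k >= 0:
            dr, dc = _D8[k]
            area[r + dr, c + dc] += area[r, c]
    return area


def mrvbf(dem: np.ndarray, cell_m: float, initial_slope_threshold_pct: float = 16.0,
          n_steps: int = 3) -> np.ndarray:
    """Multiresolution valley-bottom flatness index.

    At each step a flatness score (sigmoid of percent slope against a
    threshold that halves every step) is combined multiplicatively with
    a lowness score (sigmoid of the fraction of neighbors lower than the
    cell, over a window that triples every step, on a progressively
    smoothed DEM), and the products are accumulated. Flat, low, wide
    valley bottoms score high; steep or elevated terrain scores near 0.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if initial_slope_threshold_pct <= 0:
        raise ValueError("slope threshold must be positive")
    dem = np.asarray(dem, dtype=float)
    score = np.zeros_like(dem)
    threshold = float(initial_slope_threshold_pct)
    window = 5
    smoothed = dem
    for step in range(n_steps):
        # resolution-aware flatness: at step i a cell counts as flat
        # only if its whole 3^i-cell neighborhood is gentle, so narrow
        # floors squeezed between steep walls stop scoring as the
        # scale grows while wide floors keep their score
        slope = slope_percent(smoothed, cell_m)
        if step > 0:
            slope = ndimage.maximum_filter(slope, size=2 * 3**step + 1, mode="nearest")
        flatness = 1.0 / (1.0 + (slope / threshold) ** 4)
        pctl = _fraction_lower(smoothed, window)
        lowness = 1.0 / (1.0 + (pctl / 0.4) ** 3)
        score += flatness * lowness
        threshold /= 2.0
        window *= 3
        smoothed = ndimage.gaussian_filter(smoothed, sigma=2.0 * (step + 1), mode="nearest")
    return score


def _fraction_lower(z: np.ndarray, window: int) -> np.ndarray:
    """Fraction of in-window neighbors strictly lower than the center cell."""
    half = window // 2
    padded = np.pad(z, half, mode="constant", constant_values=np.nan)
    nr, nc = z.shape
    lower = np.zeros_like(z)
    valid = np.zeros_like(z)
    for dr in range(-half, half + 1):
        for dc in range(-half, half + 1):
            if dr == 0 and dc == 0:
                continue
            shifted = padded[half + dr:half + dr + nr, half + dc:half + dc + nc]
            ok = ~np.isnan(shifted)
            lower += ok & (shifted < z)
            valid += ok
    return lower / np.maximum(valid, 1)


def compute_terrain(dem: np.ndarray, cell_m: float, vrm_windows: tuple[int, int] = (3, 19),
                    mrvbf_steps: int = 3) -> TerrainStack:
    """Derive the full terrain predictor stack from a raw DEM.

    The second VRM window defaults to 19 cells: the nominal 18-cell
    neighborhood is even, and a centered moving window needs an odd
    size, so the nearest odd width is used.
    """
    filled = fill_sinks(dem)
    return TerrainStack(
        filled_dem=filled,
        slope_pct=slope_percent(dem, cell_m),
        vrm3=vrm(dem, cell_m, vrm_windows[0]),
        vrm18=vrm(dem, cell_m, vrm_windows[1]),
        mrvbf=mrvbf(dem, cell_m, n_steps=mrvbf_steps),
        catch_area=flow_accumulation_d8(filled, cell_m),
    )
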