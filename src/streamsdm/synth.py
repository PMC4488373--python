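"""Synthetic study systems with known ground truth.

Generates everything the pipeline consumes — a stream-bearing terrain,
spatially autocorrelated climate fields, soil composition surfaces,
two-season 6-band reflectance driven by a vegetation field, a known
logistic suitability surface, and spatially biased occurrence sampling
with effort-based survey records — so every downstream stage can be
exercised, and the fitted models checked against truth, without any
GIS downloads.

Noise fields are Gaussian random fields approximated by Gaussian-
filtered white noise; only the autocorrelation range matters for the
pipeline, not the exact covariance model. Every generator is a pure
function of (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString

from streamsdm._seeds import derive_seed, rng_for
from streamsdm import terrain as _terrain
from streamsdm.labels import BiasSurface
from streamsdm.units import SampleUnitGrid, StreamNetwork

# endmember reflectance spectra for TM-like bands 1,2,3,4,5,7
BARE_SOIL_SPECTRUM = np.array([0.14, 0.16, 0.22, 0.30, 0.38, 0.32])
VEGETATION_SPECTRUM = np.array([0.04, 0.07, 0.04, 0.45, 0.22, 0.10])
# moisture darkens the shortwave-infrared bands (5 and 7) most
MOISTURE_DEPRESSION = np.array([0.01, 0.01, 0.02, 0.03, 0.20, 0.18])

#: dry-season canopies carry less green leaf area than wet-season ones
DRY_SEASON_VEGETATION_FACTOR = 0.6

#: default generating coefficients: valley-bottom flatness (+), %sand (+),
#: elevation (-), annual precipitation (-), vegetation density (-)
DEFAULT_BETA = (2.0, 2.0, -1.5, -0.5, -1.0)
DEFAULT_BETA0 = -3.5
#: a strong-signal variant (sharper niche, rarer habitat) for
#: signal-recovery experiments
STRONG_BETA = (4.0, 4.0, -3.0, -1.0, -2.0)
STRONG_BETA0 = -7.0

CLIMATE_FAMILIES = ("Ppt", "TMn", "TMx")
DEFAULT_LAPSE_RATES = {"Ppt": 0.05, "TMn": -0.006, "TMx": -0.0065}
DEFAULT_INTERCEPTS = {"Ppt": 40.0, "TMn": 8.0, "TMx": 24.0}
# seasonal amplitude of each family around its annual mean
SEASONAL_AMPLITUDE = {"Ppt": 0.9, "TMn": 5.0, "TMx": 7.0}


@dataclass
class SyntheticLandscape:
    """A complete generated study system with its generating truth."""

    dem: np.ndarray
    cell_m: float
    covariates: dict[str, np.ndarray]
    reflectance: dict[str, np.ndarray]  # season -> (6, nr, nc) stack
    vegetation: np.ndarray
    moisture: np.ndarray
    suitability: np.ndarray
    truth: dict  # {"beta": [...], "beta0": float, "features": [names]}
    seed: int
    streams: StreamNetwork | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# low-level field generators
# ---------------------------------------------------------------------------

def smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                 range_m: float, cell_m: float) -> np.ndarray:
    """Unit-variance autocorrelated noise field.

    White noise filtered with a Gaussian kernel whose width is set so
    the semivariogram reaches 95% of its sill near ``range_m``
    (range ~ 3.46 sigma_kernel for a Gaussian-filtered field), then
    rescaled to standard deviation 1.
    """
    sigma = max(range_m / cell_m / 3.46, 1e-9)
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    z -= z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def generate_dem(seed: int, nrows: int, ncols: int, cell_m: float,
                 roughness: float = 5.0, trend: tuple[float, float] = (0.002, 0.01),
                 noise_range_m: float | None = None) -> np.ndarray:
    """Planar-trend elevation plus autocorrelated relief.

    ``trend`` is the (d z/d x, d z/d y) gradient in m/m with y pointing
    north (up); ``roughness`` is the standard deviation (m) of the
    detrended relief.
    """
    if nrows < 8 or ncols < 8:
        raise ValueError("nrows and ncols must be >= 8")
    if cell_m <= 0:
        raise ValueError("cell_m must be positive")
    if roughness < 0:
        raise ValueError("roughness must be nonnegative")
    rng = rng_for(seed, "dem")
    x = (np.arange(ncols) + 0.5) * cell_m
    y_north = (nrows - 0.5 - np.arange(nrows)) * cell_m  # row 0 is northernmost
    plane = trend[0] * x[None, :] + trend[1] * y_north[:, None]
    if roughness == 0:
        return plane
    rng_range = noise_range_m if noise_range_m is not None else 8 * cell_m
    return plane + roughness * smooth_noise(rng, (nrows, ncols), rng_range, cell_m)


def generate_covariates(dem: np.ndarray, seed: int, cell_m: float = 25.0,
                        lapse_rates: dict[str, float] | None = None,
                        noise_range_m: float = 1500.0,
                        noise_amplitude: float = 1.0,
                        coarse_factor: int = 32) -> dict[str, np.ndarray]:
    """Climate and soil covariate stack registered to the DEM.

    Climate (monthly + annual precipitation and min/max temperature,
    named ``Ppt01``..``Ppt13`` etc., ``13`` = annual) is generated on a
    coarse lattice (``coarse_factor`` DEM cells, emulating an ~800 m
    climate-surface resolution) as intercept + lapse_rate x elevation +
    seasonal cycle + smooth noise, then block-replicated to DEM
    resolution. Soil fractions (%sand/%silt/%clay) come from smoothed
    composition fields renormalized to sum exactly 100, plus a
    water-storage capacity field.
    """
    lapse = dict(DEFAULT_LAPSE_RATES)
    if lapse_rates:
        for k, v in lapse_rates.items():
            if k not in CLIMATE_FAMILIES:
                raise ValueError(f"unknown climate variable family: {k!r}")
            lapse[k] = v
    dem = np.asarray(dem, dtype=float)
    if not np.all(np.isfinite(dem)):
        raise ValueError("dem must be finite")
    nr, nc = dem.shape
    rng = rng_for(seed, "covariates")
    # coarse lattice of the climate surfaces
    cnr = int(np.ceil(nr / coarse_factor))
    cnc = int(np.ceil(nc / coarse_factor))
    dem_coarse = np.zeros((cnr, cnc))
    for i in range(cnr):
        for j in range(cnc):
            dem_coarse[i, j] = dem[i * coarse_factor:(i + 1) * coarse_factor,
                                   j * coarse_factor:(j + 1) * coarse_factor].mean()
    out: dict[str, np.ndarray] = {}
    coarse_cell = cell_m * coarse_factor
    for fam in CLIMATE_FAMILIES:
        base_noise = smooth_noise(rng, (cnr, cnc), noise_range_m, coarse_cell)
        for month in range(1, 14):
            if month == 13:
                season = 0.0  # annual value
            else:
                season = np.cos(2 * np.pi * (month - 1) / 12.0)
            fld = (DEFAULT_INTERCEPTS[fam]
                   + lapse[fam] * dem_coarse
                   + SEASONAL_AMPLITUDE[fam] * season
                   + noise_amplitude * base_noise)
            if fam == "Ppt":
                fld = np.clip(fld, 0.0, None)
            full = np.kron(fld, np.ones((coarse_factor, coarse_factor)))[:nr, :nc]
            out[f"{fam}{month:02d}"] = full
    # soil composition: smooth log-ratio fields -> softmax -> percent
    raw = np.stack([noise_amplitude * smooth_noise(rng, (nr, nc), noise_range_m, cell_m)
                    for _ in range(3)])
    raw[0] += 0.5  # sand-rich valleys on average
    expv = np.exp(raw - raw.max(axis=0, keepdims=True))
    frac = expv / expv.sum(axis=0, keepdims=True)
    out["Sand"], out["Silt"], out["Clay"] = (100.0 * frac[k] for k in range(3))
    # exact closure (guards against accumulated float error)
    total = out["Sand"] + out["Silt"] + out["Clay"]
    out["Sand"] *= 100.0 / total
    out["Silt"] *= 100.0 / total
    out["Clay"] = 100.0 - out["Sand"] - out["Silt"]
    out["WaterSt"] = np.clip(
        10.0 + 0.08 * out["Clay"] + 2.0 * smooth_noise(rng, (nr, nc), noise_range_m, cell_m),
        0.0, None)
    return out


def true_suitability(features: np.ndarray, beta: np.ndarray, beta0: float) -> np.ndarray:
    """Logistic suitability s = 1 / (1 + exp(-(beta0 + beta . x))).

    ``features`` has shape (k, ...) with one leading axis per
    coefficient.
    """
    features = np.asarray(features, dtype=float)
    beta = np.asarray(beta, dtype=float).ravel()
    if features.shape[0] != beta.size:
        raise ValueError(f"feature count {features.shape[0]} != coefficient count {beta.size}")
    eta = beta0 + np.tensordot(beta, features, axes=(0, 0))
    return 1.0 / (1.0 + np.exp(-eta))


def generate_reflectance(vegetation: np.ndarray, moisture: np.ndarray, seed: int,
                         noise_sd: float = 0.01) -> dict[str, np.ndarray]:
    """Two-season 6-band reflectance stacks in [0, 1].

    Each pixel is a linear mix of bare-soil and green-vegetation
    endmember spectra weighted by vegetation density, with a
    moisture-driven depression of the shortwave-infrared bands and
    seeded sensor noise. One vegetation field drives both seasons; the
    dry season sees it scaled by ``DRY_SEASON_VEGETATION_FACTOR``.
    """
    vegetation = np.asarray(vegetation, dtype=float)
    moisture = np.asarray(moisture, dtype=float)
    if vegetation.shape != moisture.shape:
        raise ValueError("vegetation and moisture grids must share a shape")
    rng = rng_for(seed, "reflectance")
    out = {}
    for season, vf, mf in (("wet", 1.0, 1.0), ("dry", DRY_SEASON_VEGETATION_FACTOR, 0.5)):
        v = np.clip(vegetation * vf, 0.0, 1.0)
        m = np.clip(moisture * mf, 0.0, 1.0)
        bands = (BARE_SOIL_SPECTRUM[:, None, None] * (1.0 - v)
                 + VEGETATION_SPECTRUM[:, None, None] * v
                 - MOISTURE_DEPRESSION[:, None, None] * m)
        if noise_sd > 0:
            bands = bands + rng.normal(0.0, noise_sd, bands.shape)
        out[season] = np.clip(bands, 0.0, 1.0)
    return out


def generate_streams(dem: np.ndarray, cell_m: float, accum_threshold_cells: int = 120
                     ) -> StreamNetwork:
    """Channel network extracted from the DEM by D8 flow accumulation.

    Cells whose catchment exceeds the threshold are channel cells; each
    becomes a polyline segment to its downstream neighbor's center.
    Segment order is a coarse log2 of accumulation relative to the
    threshold (>= 1).
    """
    filled = _terrain.fill_sinks(dem)
    acc = _terrain.flow_accumulation_d8(filled, cell_m)
    direction = _terrain.d8_directions(filled)
    nr, nc = dem.shape
    thresh_area = accum_threshold_cells * cell_m**2
    segs, orders = [], []
    y0 = nr * cell_m  # grid origin at upper-left, row 0 north
    for r in range(nr):
        for c in range(nc):
            if acc[r, c] < thresh_area or direction[r, c] < 0:
                continue
            dr, dc = _terrain._D8[direction[r, c]]
            x1, y1 = (c + 0.5) * cell_m, y0 - (r + 0.5) * cell_m
            x2, y2 = (c + dc + 0.5) * cell_m, y0 - (r + dr + 0.5) * cell_m
            segs.append(LineString([(x1, y1), (x2, y2)]))
            orders.append(1 + int(np.log2(acc[r, c] / thresh_area)))
    return StreamNetwork(segs, orders)


def sample_occurrences(suitability: np.ndarray, units: SampleUnitGrid, n_records: int,
                       bias: BiasSurface | str = "uniform", seed: int = 0,
                       date_range: tuple[int, int] = (1990, 2013),
                       accuracy_levels: tuple[tuple[float, float], ...] = ((30.0, 0.8), (200.0, 0.2)),
                       cell_m: float | None = None) -> pd.DataFrame:
    """Spatially biased presence records.

    Units are drawn (with replacement) with probability proportional to
    mean in-unit suitability times the sampling-bias weight; each record
    gets a coordinate jittered within its unit, a uniform year in
    ``date_range`` and a positional accuracy drawn from a two-point
    distribution (default {30 m: 0.8, 200 m: 0.2}, so an accuracy
    filter at 160 m has bite).
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    uids = units.uids
    if not uids:
        raise ValueError("unit grid is empty")
    # pixel size of the suitability raster: inferred from the grid extent
    px = cell_m if cell_m is not None else units.nrows * units.cell_m / suitability.shape[0]
    suit = np.empty(len(uids))
    for i, u in enumerate(uids):
        r, c = units.rc(u)
        rr0 = int(r * units.cell_m / px)
        cc0 = int(c * units.cell_m / px)
        k = max(int(units.cell_m / px), 1)
        block = suitability[rr0:rr0 + k, cc0:cc0 + k]
        suit[i] = block.mean() if block.size else 0.0
    if isinstance(bias, str):
        if bias != "uniform":
            raise ValueError("bias must be a BiasSurface or 'uniform'")
        bw = np.ones(len(uids))
    else:
        bw = bias.weights.reindex(uids).fillna(0.0).to_numpy()
    w = suit * bw
    if w.sum() <= 0:
        raise ValueError("all sampling weights are zero")
    rng = np.random.default_rng(derive_seed(seed, "occurrences"))
    drawn = rng.choice(len(uids), size=n_records, replace=True, p=w / w.sum())
    acc_vals = np.array([a for a, _ in accuracy_levels])
    acc_p = np.array([p for _, p in accuracy_levels])
    recs = []
    for i in drawn:
        r, c = units.rc(uids[i])
        cx, cy = units.center((r, c))
        jx, jy = rng.uniform(-0.49, 0.49, 2) * units.cell_m
        recs.append({
            "x": cx + jx,
            "y": cy + jy,
            "year": int(rng.integers(date_range[0], date_range[1] + 1)),
            "accuracy_m": float(rng.choice(acc_vals, p=acc_p / acc_p.sum())),
            "source": "synthetic",
        })
    return pd.DataFrame(recs)


def sample_surveys(suitability_by_unit: pd.Series, n_units: int, seed: int,
                   detection_p: float = 0.4, occupancy_threshold: float = 0.5,
                   max_night: int = 12, max_day: int = 8) -> pd.DataFrame:
    """Standardized-survey records with imperfect detection.

    ``n_units`` units are chosen at random; each accumulates uniform
    night/day survey counts. A unit is occupied when its true
    suitability exceeds the occupancy threshold; detection across all
    visits then follows 1 - (1 - detection_p)^visits.
    """
    rng = np.random.default_rng(derive_seed(seed, "surveys"))
    uids = suitability_by_unit.index.to_numpy()
    chosen = rng.choice(uids, size=min(n_units, len(uids)), replace=False)
    rows = []
    for u in chosen:
        n_night = int(rng.integers(0, max_night + 1))
        n_day = int(rng.integers(0, max_day + 1))
        occupied = suitability_by_unit.loc[u] > occupancy_threshold
        visits = n_night + n_day
        p_det = 1.0 - (1.0 - detection_p) ** visits if occupied else 0.0
        rows.append({
            "unit_id": int(u),
            "n_night_surveys": n_night,
            "n_day_surveys": n_day,
            "detected": bool(rng.random() < p_det),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full study system
# ---------------------------------------------------------------------------

def generate_landscape(seed: int, nrows: int = 240, ncols: int = 240, cell_m: float = 25.0,
                       roughness: float = 6.0, accum_threshold_cells: int = 120,
                       beta: np.ndarray | None = None, beta0: float = DEFAULT_BETA0) -> SyntheticLandscape:
    """Generate a complete synthetic study system.

    The suitability truth is a logistic model over standardized
    valley-bottom flatness (+), %sand (+), elevation (-), annual
    precipitation (-) and vegetation density (-): open, sandy, flat
    low-elevation valley bottoms are suitable — the kind of niche the
    pipeline is meant to recover. The drivers act at landscape scale
    (valley form is smoothed to a ~200 m footprint; soils and climate
    are generated smooth), so suitable ground forms coherent patches
    rather than pixel noise, and the default intercept keeps suitable
    ground a minority of the landscape.
    """
    dem = generate_dem(seed, nrows, ncols, cell_m, roughness=roughness)
    covs = generate_covariates(dem, seed, cell_m=cell_m)
    filled = _terrain.fill_sinks(dem)
    mrv = _terrain.mrvbf(dem, cell_m)
    slope = _terrain.slope_percent(dem, cell_m)
    rng = rng_for(seed, "vegetation")
    moisture = np.clip(0.5 + 0.25 * smooth_noise(rng, dem.shape, 2000.0, cell_m), 0.0, 1.0)
    vegetation = np.clip(
        0.25 + 0.45 * moisture + 0.2 * smooth_noise(rng, dem.shape, 1000.0, cell_m), 0.0, 1.0)

    def z(a: np.ndarray) -> np.ndarray:
        return (a - a.mean()) / (a.std() + 1e-12)

    smooth_px = max(200.0 / cell_m, 1.0)
    mrv_s = ndimage.gaussian_filter(mrv, smooth_px, mode="nearest")
    feature_grids = np.stack([z(mrv_s), z(covs["Sand"]), z(dem), z(covs["Ppt13"]),
                              z(vegetation)])
    if beta is None:
        beta = np.array(DEFAULT_BETA)
    suit = true_suitability(feature_grids, beta, beta0)
    refl = generate_reflectance(vegetation, moisture, seed)
    streams = generate_streams(dem, cell_m, accum_threshold_cells)
    return SyntheticLandscape(
        dem=dem, cell_m=cell_m, covariates=covs, reflectance=refl,
        vegetation=vegetation, moisture=moisture, suitability=suit,
        truth={"beta": np.asarray(beta).tolist(), "beta0": float(beta0),
               "features": ["mrvbf_z", "sand_z", "elev_z", "ppt_annual_z", "vegetation_z"]},
        seed=int(seed), streams=streams,
        extras={"filled_dem": filled, "mrvbf": mrv, "slope_pct": slope},
    )
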