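"""Presence/absence labelling and bias-matched pseudoabsence sampling.

Occurrence records are filtered (stream buffer, positional accuracy,
date window) and mapped to sample units as presences; survey records
yield verified absences where effort was sufficient and the species was
never detected (a presence in the same unit always wins). Because
locality data carry spatial sampling bias, pseudoabsences are drawn
from a kernel-density surface fitted to the presence units, so the
background shares the presences' bias rather than fighting it.
Balanced replicate training sets pair every presence with a negative
(verified absence first, bias-matched pseudoabsence for the remainder).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from shapely.geometry import Point

from streamsdm._seeds import derive_seed
from streamsdm.units import SampleUnitGrid, StreamNetwork

log = logging.getLogger(__name__)


@dataclass
class LabelSet:
    """Disjoint presence and verified-absence unit-id sets for one model."""

    presence_units: set[int]
    absence_units: set[int] = field(default_factory=set)
    model_tag: str = ""

    def __post_init__(self) -> None:
        if self.presence_units & self.absence_units:
            raise ValueError("presence and absence sets overlap")


@dataclass
class BiasSurface:
    """Per-unit sampling-bias weights (nonnegative, summing to 1)."""

    weights: pd.Series  # indexed by unit_id
    bandwidth_m: float

    def __post_init__(self) -> None:
        w = self.weights
        if (w < 0).any():
            raise ValueError("bias weights must be nonnegative")
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("bias weights must sum to 1")


@dataclass
class TrainingSet:
    """One balanced replicate: unit ids with labels and label provenance."""

    replicate_id: int
    rows: pd.DataFrame  # columns: unit_id, label (1/0), label_source

    def __post_init__(self) -> None:
        n1 = int((self.rows["label"] == 1).sum())
        n0 = int((self.rows["label"] == 0).sum())
        if n1 != n0:
            raise ValueError(f"training set not balanced: {n1} presences vs {n0} negatives")


def assign_presences(records: pd.DataFrame, streams: StreamNetwork, grid: SampleUnitGrid,
                     buffer_m: float = 50.0, max_accuracy_m: float = 160.0,
                     date_window: tuple[int, int] | None = None) -> set[int]:
    """Filter occurrence records and map them to presence units.

    Keeps records within ``buffer_m`` of the stream network, with
    documented accuracy <= ``max_accuracy_m`` (records of unknown
    accuracy are retained), and with year inside ``date_window``
    (inclusive) when given. Surviving records are deduplicated to the
    set of containing sample units; records outside the grid are
    dropped with a log entry.
    """
    stream_union = streams.union()
    presences: set[int] = set()
    n_out = 0
    for rec in records.itertuples(index=False):
        acc = getattr(rec, "accuracy_m", None)
        if acc is not None and np.isfinite(acc) and acc > max_accuracy_m:
            continue
        if date_window is not None:
            year = int(getattr(rec, "year", getattr(rec, "date", 0)))
            if not date_window[0] <= year <= date_window[1]:
                continue
        p = Point(rec.x, rec.y)
        if stream_union.is_empty or stream_union.distance(p) > buffer_m:
            continue
        rc = grid.contains_xy(rec.x, rec.y)
        if rc is None or rc not in grid.unit_ids:
            n_out += 1
            continue
        presences.add(grid.uid(rc))
    if n_out:
        log.info("dropped %d records outside the unit lattice", n_out)
    return presences


def derive_absences(surveys: pd.DataFrame, presences: set[int],
                    min_night: int = 8, min_day: int = 5) -> set[int]:
    """Verified-absence units from survey effort.

    A unit is an absence iff it accumulated at least ``min_night``
    nighttime surveys or ``min_day`` daytime surveys with no detection
    ever — and has no presence record (presence takes priority).
    """
    if len(surveys) == 0:
        return set()
    agg = surveys.groupby("unit_id").agg(
        n_night=("n_night_surveys", "sum"),
        n_day=("n_day_surveys", "sum"),
        detected=("detected", "any"),
    )
    enough = (agg["n_night"] >= min_night) | (agg["n_day"] >= min_day)
    absent = agg.index[enough & ~agg["detected"]]
    return set(int(u) for u in absent) - set(presences)


def default_kde_bandwidth(presence_units: set[int], grid: SampleUnitGrid) -> float:
    """Scale-adaptive default: 2x the median nearest-neighbor distance
    among presence unit centers (falls back to one cell size)."""
    uids = sorted(presence_units)
    if len(uids) < 2:
        return float(grid.cell_m)
    pts = grid.centers(uids)
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    return float(2.0 * np.median(d.min(axis=1)))


def kde_bias_surface(presence_units: set[int], grid: SampleUnitGrid,
                     bandwidth_m: float | None = None,
                     candidates: set[int] | None = None) -> BiasSurface:
    """Gaussian kernel density of presence unit centers over candidate units.

    Doubly edge/availability corrected: each presence kernel is
    renormalized to unit mass over the candidate units (so boundary
    presences do not lose mass off the study area), and the summed
    density at each candidate is divided by the local candidate
    coverage (the kernel-weighted amount of candidate area around it),
    so irregular unit geometry does not masquerade as sampling bias.
    The result is normalized to sum 1.
    """
    if not presence_units:
        raise ValueError("need at least one presence unit")
    if bandwidth_m is None:
        bandwidth_m = default_kde_bandwidth(presence_units, grid)
    if bandwidth_m <= 0:
        raise ValueError("bandwidth_m must be positive")
    cand = sorted(candidates) if candidates is not None else grid.uids
    pres_pts = grid.centers(sorted(presence_units))
    cand_pts = grid.centers(cand)
    d2 = cdist(cand_pts, pres_pts, "sqeuclidean")
    k = np.exp(-d2 / (2.0 * bandwidth_m**2))
    kernel_mass = k.sum(axis=0)
    if np.any(kernel_mass <= 0) or not np.all(np.isfinite(kernel_mass)):
        raise ValueError("bias surface has zero total weight; try a larger bandwidth")
    density = (k / kernel_mass).sum(axis=1)
    coverage = np.empty(len(cand))
    for lo in range(0, len(cand), 512):  # chunked cand x cand kernel
        block = cdist(cand_pts[lo:lo + 512], cand_pts, "sqeuclidean")
        coverage[lo:lo + 512] = np.exp(-block / (2.0 * bandwidth_m**2)).sum(axis=1)
    w = density / coverage
    return BiasSurface(pd.Series(w / w.sum(), index=cand), float(bandwidth_m))


def draw_pseudoabsences(candidates: set[int], bias: BiasSurface, n: int, seed: int) -> set[int]:
    """Weighted sampling of background units without replacement."""
    cand = sorted(candidates)
    w = bias.weights.reindex(cand).fillna(0.0).to_numpy()
    positive = int((w > 0).sum())
    if n > positive:
        raise ValueError(f"requested {n} pseudoabsences but only {positive} "
                         f"candidates have positive weight")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(cand, size=n, replace=False, p=w / w.sum())
    return set(int(u) for u in chosen)


def build_replicates(labels: LabelSet, bias: BiasSurface, grid: SampleUnitGrid,
                     n_replicates: int = 10, seed: int = 0,
                     include_absences_in_pool: bool = False) -> list[TrainingSet]:
    """Balanced replicate training sets with replicate-specific pseudoabsences.

    Each replicate contains every presence (label 1), every verified
    absence (label 0) and ``|presence| - |absence|`` pseudoabsences
    (label 0) drawn from the bias surface with a per-replicate sub-seed.
    Verified-absence units are excluded from the pseudoabsence pool by
    default (they are already negatives).
    """
    n_pres, n_abs = len(labels.presence_units), len(labels.absence_units)
    n_pseudo = n_pres - n_abs
    if n_pseudo < 0:
        log.warning("more verified absences than presences; drawing no pseudoabsences")
        n_pseudo = 0
    pool = set(grid.uids) - labels.presence_units
    if not include_absences_in_pool:
        pool -= labels.absence_units
    out = []
    for rep in range(1, n_replicates + 1):
        pseudo = draw_pseudoabsences(pool, bias, n_pseudo, derive_seed(seed, "pseudoabsence", rep)) \
            if n_pseudo else set()
        rows = pd.DataFrame(
            [(u, 1, "presence") for u in sorted(labels.presence_units)]
            + [(u, 0, "absence") for u in sorted(labels.absence_units)]
            + [(u, 0, "pseudoabsence") for u in sorted(pseudo)],
            columns=["unit_id", "label", "label_source"],
        )
        out.append(TrainingSet(rep, rows))
    return out
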