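"""End-to-end orchestration of the dual-model analysis.

``simulate_study`` builds a complete synthetic study system;
``run_model`` executes one model branch (units -> terrain/spectral ->
features -> PCA -> labels -> forest ensemble -> evaluation) and
``run_integration`` differences the two binary predictions into the
transition map and headline summary. All stages derive their
randomness from the single config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from streamsdm import synth
from streamsdm._seeds import derive_seed, rng_for
from streamsdm.ensemble import (EnsemblePrediction, ModelConfig, fit_ensemble,
                                importance_summary, predict_ensemble)
from streamsdm.evaluate import EvaluationReport, evaluate_model, min_presence_threshold, \
    binarize, permutation_test
from streamsdm.features import FeatureTable, aggregate_layers, pca_fit, pca_transform, stream_slope
from streamsdm.integrate import BinaryMap, SummaryReport, TransitionMap, conserved_overlay, \
    summarize, transition_map
from streamsdm.labels import (BiasSurface, LabelSet, assign_presences, build_replicates,
                              derive_absences, kde_bias_surface)
from streamsdm.spectral import ReflectanceStack, dos1_correct, tasseled_cap
from streamsdm.terrain import TerrainStack, compute_terrain
from streamsdm.units import SampleUnitGrid, StreamNetwork, build_units, filter_streams, mask_water

log = logging.getLogger(__name__)

SEASON_CODES = {"wet": "03", "dry": "09"}  # imagery month tags per season


@dataclass
class StudySystem:
    """A simulated study area ready for the modelling pipeline."""

    landscape: synth.SyntheticLandscape
    grid: SampleUnitGrid
    streams: StreamNetwork
    terrain: TerrainStack
    occurrences: pd.DataFrame
    surveys: pd.DataFrame
    conserved: list
    suitability_by_unit: pd.Series
    seed: int


@dataclass
class RunConfig:
    """Settings for one model run."""

    model_tag: str = "potential"  # "potential" or "current"
    buffer_m: float = 50.0
    max_accuracy_m: float = 160.0
    date_window: tuple[int, int] | None = None
    min_night: int = 8
    min_day: int = 5
    n_replicates: int = 10
    n_trees: int = 501
    kde_bandwidth_m: float | None = None
    n_perm: int = 0
    perm_trees: int = 101
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_tag not in ("potential", "current"):
            raise ValueError("model_tag must be 'potential' or 'current'")


@dataclass
class ModelRun:
    """Artifacts of one executed model branch."""

    config: RunConfig
    features: FeatureTable
    scores: FeatureTable
    pca: object
    labels: LabelSet
    bias: BiasSurface
    prediction: EnsemblePrediction
    evaluation: EvaluationReport
    importance: pd.DataFrame
    binary: BinaryMap
    manifest: dict
    models: list = field(default_factory=list)


def simulate_study(seed: int, nrows: int = 240, ncols: int = 240, cell_m: float = 25.0,
                   unit_cell_m: float = 200.0, n_records: int = 600,
                   n_survey_units: int = 40, accum_threshold_cells: int = 120,
                   sampling_bias: str = "focal", **landscape_kw) -> StudySystem:
    """Generate a landscape and the observational data of a field study.

    Occurrence sampling is spatially biased by default ("focal"): effort
    concentrates around a seeded focal point, emulating the clustered
    survey coverage of real locality compilations. Conserved-land
    polygons cover a seeded subset of the area.
    """
    land = synth.generate_landscape(seed, nrows, ncols, cell_m,
                                    accum_threshold_cells=accum_threshold_cells, **landscape_kw)
    origin = (0.0, nrows * cell_m)
    gridrows = int(np.ceil(nrows * cell_m / unit_cell_m))
    gridcols = int(np.ceil(ncols * cell_m / unit_cell_m))
    # drop low-order fragments, as with unordered headwater segments
    ordered = StreamNetwork(
        [s for s, o in zip(land.streams.segments, land.streams.order) if o and o >= 1],
        [o for o in land.streams.order if o and o >= 1])
    streams = filter_streams(land.streams, ordered, buffer_m=50.0)
    grid = build_units(streams, origin, unit_cell_m, gridrows, gridcols)
    grid = mask_water(grid, [])
    # per-unit mean true suitability (pixel blocks per unit)
    k = int(unit_cell_m / cell_m)
    suit = {}
    for u in grid.uids:
        r, c = grid.rc(u)
        suit[u] = float(land.suitability[r * k:(r + 1) * k, c * k:(c + 1) * k].mean())
    suit = pd.Series(suit)
    # spatially concentrated sampling effort
    if sampling_bias == "focal":
        rng = rng_for(seed, "occurrences", 1)
        centers = grid.centers(grid.uids)
        focal = centers[rng.integers(0, len(centers))]
        sigma = max(nrows, ncols) * cell_m / 3.0
        w = np.exp(-((centers - focal) ** 2).sum(axis=1) / (2 * sigma**2))
        bias = BiasSurface(pd.Series(w / w.sum(), index=grid.uids), sigma)
    else:
        bias = "uniform"
    occ = synth.sample_occurrences(land.suitability, grid, n_records, bias=bias, seed=seed)
    surveys = synth.sample_surveys(suit, n_survey_units, seed)
    # conserved lands: seeded rectangles covering roughly a third of the extent
    crng = rng_for(seed, "conserved")
    extent_x, extent_y = ncols * cell_m, nrows * cell_m
    conserved = []
    for _ in range(3):
        w_, h_ = crng.uniform(0.2, 0.4, 2) * (extent_x, extent_y)
        x0 = crng.uniform(0, extent_x - w_)
        y0 = crng.uniform(0, extent_y - h_)
        conserved.append(box(x0, y0, x0 + w_, y0 + h_))
    terr = compute_terrain(land.dem, cell_m)
    return StudySystem(land, grid, streams, terr, occ, surveys, conserved, suit, int(seed))


def build_feature_table(study: StudySystem, model_tag: str = "potential") -> FeatureTable:
    """Assemble the per-unit environmental variable table.

    Aggregation rules follow the variable class: majority for the
    coarse climate surfaces, (area-weighted) means for soil, minimum
    for elevation and ruggedness, maximum for valley-bottom flatness
    and catchment area, median and variance for the Tasseled Cap
    indices; stream slope is computed from the DEM along the in-unit
    stream length.
    """
    land, grid = study.landscape, study.grid
    layers: dict[str, np.ndarray] = {}
    rules: dict[str, str] = {}
    for name, arr in land.covariates.items():
        layers[name] = arr
        rules[name] = "area_weighted_mean" if name in ("Sand", "Silt", "Clay", "WaterSt") \
            else "majority"
    layers["Elev"] = study.terrain.filled_dem
    rules["Elev"] = "min"
    layers["MRVBF"] = study.terrain.mrvbf
    rules["MRVBF"] = "max"
    layers["VRM03"] = study.terrain.vrm3
    rules["VRM03"] = "min"
    layers["VRM18"] = study.terrain.vrm18
    rules["VRM18"] = "min"
    layers["CatchArea"] = study.terrain.catch_area
    rules["CatchArea"] = "max"
    if model_tag == "current":
        for season, stack in land.reflectance.items():
            code = SEASON_CODES[season]
            tc = tasseled_cap(dos1_correct(ReflectanceStack(stack, season)))
            for idx_name, idx in (("Brt", tc.brightness), ("Grn", tc.greenness),
                                  ("Wet", tc.wetness)):
                layers[f"{idx_name}{code}.Med"] = idx
                rules[f"{idx_name}{code}.Med"] = "median"
                layers[f"{idx_name}{code}.Var"] = idx
                rules[f"{idx_name}{code}.Var"] = "variance"
    table = aggregate_layers(grid, layers, rules, px_m=land.cell_m)
    slope = stream_slope(grid, land.dem, study.streams, px_m=land.cell_m)
    table["Slope"] = slope.reindex(table.index)
    return table


def run_model(study: StudySystem, config: RunConfig, out_dir: str | Path | None = None) -> ModelRun:
    """Execute one model branch end to end."""
    is_current = config.model_tag == "current"
    table = build_feature_table(study, config.model_tag)
    transform = pca_fit(table)
    scores = pca_transform(table, transform)

    presences = assign_presences(study.occurrences, study.streams, study.grid,
                                 buffer_m=config.buffer_m,
                                 max_accuracy_m=config.max_accuracy_m,
                                 date_window=config.date_window)
    presences &= set(scores.index)
    if not presences:
        raise RuntimeError("no presence units after filtering")
    absences = set()
    if is_current:
        absences = derive_absences(study.surveys, presences,
                                   min_night=config.min_night, min_day=config.min_day)
        absences &= set(scores.index)
    label_set = LabelSet(presences, absences, config.model_tag)
    pool = set(study.grid.uids) - presences - absences
    bias = kde_bias_surface(presences, study.grid, config.kde_bandwidth_m, candidates=pool)
    replicates = build_replicates(label_set, bias, study.grid,
                                  n_replicates=config.n_replicates, seed=config.seed)
    model_cfg = ModelConfig(n_trees=config.n_trees, n_replicates=config.n_replicates,
                            seed=config.seed)
    models = fit_ensemble(replicates, scores, model_cfg)
    prediction = predict_ensemble(models, scores)
    pseudo_union = set()
    per_rep_negs = []
    for ts in replicates:
        neg = set(ts.rows.loc[ts.rows["label"] == 0, "unit_id"])
        per_rep_negs.append(neg)
        pseudo_union |= neg
    report = evaluate_model(prediction, presences, absences | pseudo_union, per_rep_negs)
    if config.n_perm > 0:
        perm_cfg = ModelConfig(n_trees=config.perm_trees, n_replicates=config.n_replicates,
                               seed=config.seed)
        ps, bounds = [], []
        for ts in replicates:
            res = permutation_test(ts, scores, perm_cfg, config.n_perm,
                                   derive_seed(config.seed, "permutation", ts.replicate_id))
            ps.append(res.p_value)
            bounds.append(res.is_upper_bound)
        report.per_replicate_p = ps
        k = int(np.argmax(ps))
        report.p_value = ps[k]  # headline: worst replicate
        report.p_is_upper_bound = bounds[k]
    imp = importance_summary(models)
    binary = binarize(prediction, report.threshold, config.model_tag)
    manifest = {
        "model_tag": config.model_tag,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "study_seed": study.seed,
        "n_units": int(len(scores)),
        "n_presence": len(presences),
        "n_absence": len(absences),
        "n_pseudoabsence_per_replicate": int((replicates[0].rows["label_source"]
                                              == "pseudoabsence").sum()),
        "feature_columns": list(table.columns),
        "n_spectral_columns": sum(c.split(".")[-1] in ("Med", "Var") for c in table.columns),
        "pca_retained": transform.retained,
        "oob_errors": [m.oob_error for m in models],
        "kde_bandwidth_m": bias.bandwidth_m,
    }
    run = ModelRun(config, table, scores, transform, label_set, bias, prediction,
                   report, imp, binary, manifest, models)
    if out_dir is not None:
        write_run(run, out_dir)
    return run


def write_run(run: ModelRun, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pred = run.prediction.matrix.copy()
    pred.insert(0, "mean_prob", run.prediction.mean)
    pred["cv"] = run.prediction.cv
    pred.to_csv(out / "prediction.csv", index_label="unit_id")
    run.binary.values.rename("habitat").to_csv(out / "binary.csv", index_label="unit_id")
    run.importance.to_csv(out / "importance.csv", index_label="variable")
    run.features.to_csv(out / "features.csv")
    with open(out / "evaluation.json", "w") as fh:
        json.dump(run.evaluation.to_dict(), fh, indent=2)
    with open(out / "pca.json", "w") as fh:
        json.dump(run.pca.to_dict(), fh)
    m = max(run.pca.retained, 1)
    loadings = pd.DataFrame(run.pca.loadings[:, :m], index=run.pca.columns,
                            columns=[f"PC{j + 1}" for j in range(m)])
    loadings.loc["__eigenvalue__"] = run.pca.eigenvalues[:m]
    loadings.to_csv(out / "pca_loadings.csv", index_label="variable")
    with open(out / "manifest.json", "w") as fh:
        json.dump(run.manifest, fh, indent=2)


def load_binary(run_dir: str | Path) -> BinaryMap:
    p = Path(run_dir) / "binary.csv"
    if not p.exists():
        raise FileNotFoundError(f"no binary prediction at {p}")
    s = pd.read_csv(p, index_col="unit_id")["habitat"]
    return BinaryMap(s)


def run_integration(potential: ModelRun | str | Path, current: ModelRun | str | Path,
                    conserved: list | None = None, grid: SampleUnitGrid | None = None,
                    out_dir: str | Path | None = None
                    ) -> tuple[TransitionMap, SummaryReport, dict | None]:
    """Difference the two binary predictions and summarize.

    Accepts in-memory ModelRun objects or run directories written by
    ``run_model``. The conserved-lands overlay is computed when
    polygons and the unit grid are supplied.
    """
    pot = potential.binary if isinstance(potential, ModelRun) else load_binary(potential)
    cur = current.binary if isinstance(current, ModelRun) else load_binary(current)
    trans = transition_map(pot, cur)
    report = summarize(trans, pot, cur)
    overlay = None
    if conserved is not None and grid is not None:
        overlay = {
            "potential_habitat": conserved_overlay(pot, conserved, grid)["habitat"],
            "current_habitat": conserved_overlay(cur, conserved, grid)["habitat"],
            "transition_plus1": conserved_overlay(trans, conserved, grid)["plus1"],
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trans.values.rename("transition").to_csv(out / "transition.csv", index_label="unit_id")
        payload = report.to_dict()
        if overlay is not None:
            payload["conserved_overlay_pct"] = overlay
        with open(out / "summary.json", "w") as fh:
            json.dump(payload, fh, indent=2)
    return trans, report, overlay


def truth_labels(study: StudySystem, threshold: float = 0.5) -> pd.Series:
    """Ground-truth habitat labels from the generating suitability."""
    return (study.suitability_by_unit > threshold).astype(int)


def recovery_auc(prediction: EnsemblePrediction, study: StudySystem,
                 threshold: float = 0.5) -> float:
    """AUC of averaged probabilities against true-suitability labels."""
    from streamsdm.evaluate import auc as _auc

    labels = truth_labels(study, threshold)
    common = labels.index.intersection(prediction.mean.index)
    return _auc(prediction.mean.loc[common].to_numpy(), labels.loc[common].to_numpy())
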