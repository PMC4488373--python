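# streamsdm

Dual species-distribution modelling for stream-associated habitat
specialists, built around the conservation workflow developed for the
endangered arroyo toad (*Anaxyrus californicus*) in southern
California's coastal drainages: identify where a species *could* live,
where it *currently can* live, and difference the two maps to find the
sites worth restoring.

The package is a library first (importable API plus the narrative
scripts in `examples/`), with a thin `streamsdm` command-line wrapper
for staged runs.

## The method

The analysis lattice is the set of 200 m × 200 m grid cells that
intersect the stream network (small unordered headwater fragments and
open-water cells removed). Two models are fitted on per-unit
environmental variables reduced by a correlation-matrix PCA (Kaiser's
rule, eigenvalue > 1):

* **potential model** — long-term variables only: monthly climate
  (majority value per unit), soil composition (area-weighted means),
  and geomorphometry from a sink-filled DEM — minimum elevation,
  stream slope, minimum vector ruggedness (VRM, 3- and 19-cell
  windows), maximum multiresolution valley-bottom flatness (MRVBF),
  maximum D8 catchment area;
* **current model** — the same plus per-unit median and variance of
  Tasseled Cap brightness, greenness and wetness from DOS1-corrected
  two-season 6-band reflectance, and a recent-records-only label set
  with survey-verified absences (≥ 8 night or ≥ 5 day surveys, never
  detected; presence wins ties).

Each model is an ensemble of replicate Random Forests (fully grown
trees, `floor(√p)` variables per split) trained on exactly balanced
presence/negative sets; the negatives are verified absences topped up
with pseudoabsences drawn from a kernel-density surface of the
presences, so the background carries the same spatial sampling bias
as the locality data. Probability of occurrence is the averaged
class-1 vote fraction across replicates. Evaluation reports rank-based
AUC, the minimum-training-presence threshold τ (lowest averaged
probability at a confirmed presence; ≥ τ is habitat), TSS and
misclassification, and a label-permutation significance test on the
out-of-bag (OOB) error. Variable importance is OOB permutation
importance (mean decrease in accuracy).

Integration computes `T(u) = potential(u) − current(u)` per unit:
**+1** units are intrinsically suitable but not currently so — the
restoration candidates — and the summary reports habitat percentages
and the overlap of each category with conserved-land polygons.

A synthetic-landscape module (`streamsdm.synth`) generates complete
study systems — stream-bearing terrain, autocorrelated covariates,
two-season reflectance, a known logistic suitability truth, biased
occurrence sampling and survey effort — so the whole pipeline runs and
is tested with no GIS downloads. See `docs/methods.md` for the model
details and the generator's scope.

## Worked example

`examples/06_transition_map.py` simulates a 3 km × 3 km study system,
fits both models and integrates them:

```
$ python examples/06_transition_map.py
154 sample units
potential habitat: 38 units (24.68%)
current habitat:   26 units (16.88%)
+1 (restorable):   15 units (9.74% of study area)
-1 (current only): 3 units
net change potential -> current: 31.58%
restoring every +1 unit would raise current habitat by 57.69%
share of each category on conserved lands: {'potential_habitat': '18.4%',
 'current_habitat': '19.2%', 'transition_plus1': '13.3%'}
```

Reading: of 154 stream sample units, 38 are predicted suitable on
intrinsic grounds but only 26 under current land cover; the 15 units
predicted potential-but-not-current (9.74% of the study area) are the
candidate restoration sites, and only 13.3% of them already fall on
conserved land. `examples/05_fit_and_evaluate.py` prints the
model-quality side for the same landscape — back-prediction AUC and
TSS of 1.0 at threshold 0.681, per-replicate permutation p-values, the
importance ranking, and an AUC of the averaged probabilities against
the landscape's known suitability truth.

The other examples cover the individual stages: landscape generation
(`01`), terrain metrics (`02`), Tasseled Cap indices (`03`), and label
construction with the bias surface (`04`).

## Command line

```sh
streamsdm simulate --seed 4 --out sim/           # write a synthetic study system
streamsdm units --streams sim/streams.geojson --origin 0 6000 \
    --nrows 30 --ncols 30 --out units.csv        # build the sample-unit lattice
streamsdm terrain --dem sim/dem.asc --out terr/  # geomorphometric stack
streamsdm spectral --stack-prefix sim/refl_wet_ --season wet --out tc/
streamsdm run --config run.yaml --out results/   # both models + integration
streamsdm integrate --potential results/potential --current results/current \
    --out results/integration
```

`run` takes a YAML config with a `seed`, `simulate:` options for the
study system and `model:`/`potential:`/`current:` blocks of
`RunConfig` fields; every stochastic stage derives its sub-seed from
the one master seed, so reruns are byte-identical.

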