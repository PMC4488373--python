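# Methods

`streamsdm` implements a dual species-distribution-model (SDM) workflow
for stream-associated habitat specialists, with the endangered arroyo
toad's riparian niche as the motivating case: open, sandy, flat valley
bottoms at low elevation. Two balanced presence/pseudoabsence
Random-Forest ensembles are fitted — a *potential* model from
long-term environmental variables and a *current* model that adds
remotely sensed land-cover indices — and their binary predictions are
differenced into a transition map whose +1 cells are candidate
restoration sites.

## Units of analysis

The analysis lattice is a regular grid of square sample units (200 m
by default, planar projected meters). Fine-scale stream segments are
first screened against an order-bearing network: a segment is kept if
any part of it lies within 50 m of an ordered segment, absorbing
positional mismatch between datasets of different scale. A cell
becomes a sample unit when its square has a positive-length
intersection with a retained stream polyline (exact segment/box
clipping; a bare corner touch does not count). Units whose cell is
covered more than 50% by mapped water polygons are removed. The grid
is row-major, 0-based, origin at the upper-left corner; cell (r, c)
spans `[x0+c·s, x0+(c+1)·s) × (y0−(r+1)·s, y0−r·s]` (half-open), a
convention fixed here because none is standard.

## Environmental variables

Per-unit variables follow fixed aggregation rules chosen by variable
class:

| class | variables | rule |
|---|---|---|
| climate (coarse surfaces) | monthly + annual precipitation, min/max temperature (`Ppt01..13`, `TMn01..13`, `TMx01..13`) | majority value (ties → smallest) |
| soil | %sand, %silt, %clay, water-storage capacity | area-weighted mean (plain mean for equal-area pixels) |
| terrain | elevation (min), stream slope (computed), MRVBF (max), VRM 3 px and 19 px (min), catchment area (max) | as noted |
| spectral (current model only) | Tasseled Cap brightness/greenness/wetness, two seasons | median and variance (ddof = 1) |

Stream slope per unit is `100 × (max − min elevation among
stream-crossed DEM pixels) / (stream length within the unit)`, with
the crossed pixels found by sampling the clipped polyline at half-pixel
spacing.

Terrain derivatives: sinks are filled by priority-flood with a 1e-6 m
epsilon gradient so no flats survive; percent slope is
`100·‖∇z‖` from central differences (one-sided at edges); VRM is
Sappington's dispersion of unit surface normals (the nominal 18-pixel
window becomes 19 — a centered operator needs an odd width); D8 flow
accumulation routes each cell's area to its steepest-descent neighbor
with ties broken in the fixed order E, SE, S, SW, W, NW, N, NE. The
valley-bottom index follows the multiresolution flatness/lowness
recipe: at each of 3 steps (default), a flatness sigmoid
`1/(1+(slope/t)^4)` — threshold `t` starting at 16% and halving each
step — is multiplied by a lowness sigmoid of the fraction of
lower-lying neighbors in a window that triples each step, on a
progressively smoothed DEM, and the products are summed. Flatness at
step *i* uses the maximum slope within the 3^i neighborhood, so narrow
floors squeezed between steep walls stop scoring as the scale grows;
this is the resolution-coarsening of the original cascade expressed as
a moving-window operator. With the default 3 steps scores lie in
[0, 3]; the step count is configurable.

Spectral preprocessing assumes top-of-atmosphere reflectance as input.
DOS1 subtracts a per-band dark-object value — the 1% order statistic
rather than the absolute minimum, so a single dark artifact cannot set
the offset — and clips at zero. The Tasseled Cap transform uses the
published TM reflectance coefficient set shipped as a versioned YAML
config (`streamsdm/data/tasseled_cap_tm.yaml`), swappable for other
sensor generations.

The variable table is reduced by PCA on the correlation matrix,
retaining components with eigenvalue strictly greater than 1
(Kaiser's rule). Eigenvector signs are fixed by forcing each
component's largest-magnitude loading positive; signs are otherwise
arbitrary and would not reproduce across runs. The PCA is fitted on
sample units only.

## Labels

Occurrence records are kept when they lie within 50 m of the stream
network, carry documented accuracy ≤ 160 m (unknown accuracy is
retained — only documented poor accuracy is disqualifying), and fall
in the model's date window (none for the potential model, 2005–2013
for the current model). Surviving records deduplicate to presence
units. Survey records yield verified absences where a unit accumulated
at least 8 night or 5 day surveys with no detection ever; a presence
record in the same unit always wins.

Because locality compilations are spatially biased, pseudoabsences are
drawn from a Gaussian kernel density of the presence unit centers so
the background carries the same bias. The estimator is doubly
corrected: each presence kernel is renormalized to unit mass over the
candidate units (boundary presences do not lose mass off the study
area), and the summed density is divided by the local candidate
coverage so irregular corridor geometry is not mistaken for sampling
bias. The default bandwidth is twice the median nearest-neighbor
distance among presence centers — scale-adaptive and appropriate when
effort is clustered. When effort is known to be near-uniform (as in
the synthetic recovery experiments) a broad bandwidth of about a
quarter of the grid extent should be passed instead
(`kde_bandwidth_m`); a tight kernel there would concentrate the
background right next to the presences and erase the environmental
contrast the model needs — the classic failure mode of target-group
background sampling under weak bias.

Each of the R replicates (default 10) contains every presence (1),
every verified absence (0) and `|presence| − |absence|`
pseudoabsences (0) drawn without replacement with a replicate-specific
sub-seed, so training sets are exactly balanced. Verified-absence
units are excluded from the pseudoabsence pool by default. All
sub-seeds derive from one master seed via a fixed splitting rule
(`numpy.random.SeedSequence` over stage/replicate keys), so stage
order never changes the randomness any stage sees.

## Ensemble, evaluation, integration

Each replicate is a classification forest of fully grown trees
(scikit-learn `RandomForestClassifier`), one bootstrap sample per
tree and `floor(√p)` candidate variables per split. The documented
field default is 10,001 trees; tests and desk-scale runs use 101–501,
which is past the point where OOB error stabilizes at these problem
sizes. Per-unit probability of occurrence is the class-1 vote
fraction, averaged across replicates; the per-unit coefficient of
variation across replicates maps between-replicate uncertainty. OOB
error aggregates, for each training row, the votes of only those
trees whose bootstrap excluded it. Variable importance is OOB
permutation importance (mean decrease in accuracy), computed per tree
with independent permutations and averaged — the convention of the
classical randomForest implementation, computed here from the trees'
bootstrap indices because scikit-learn does not expose it.

Evaluation reports: rank-based AUC of the averaged probabilities
(presences against pooled negatives — verified absences plus the
union of all replicates' pseudoabsences; per-replicate AUCs are also
kept); the minimum-training-presence threshold (lowest averaged
probability at a confirmed presence; probability equal to the
threshold counts as habitat, so every defining presence back-predicts
as habitat); TSS (sensitivity + specificity − 1) and the
misclassification rate from the 2×2 table. Significance is a label
permutation test: the forest is refitted `n_perm` times on permuted
labels and `p = (# null OOB errors strictly below observed)/n_perm`;
"strictly below" makes ties count against significance, and a zero
count is reported as the upper bound `p < 1/n_perm`, keeping p in
(0, 1]. It is run per replicate; the headline is the worst replicate.

Integration subtracts the current binary map from the potential one:
+1 flags restorable units, −1 the reverse, 0 no change. The summary
reports percentages rounded to two decimals with full precision kept
alongside (`n(+1) − n(−1) = |P| − |C|` always). The conserved-lands
overlay counts a unit as protected when polygons cover more than half
its cell (threshold configurable).

## The synthetic study system

`synth` generates everything the pipeline consumes, as pure functions
of (seed, parameters). Noise fields are Gaussian-filtered white noise,
centered and scaled to unit variance, with the kernel width set so the
variogram range (95% of sill) matches the requested autocorrelation
length — only that range matters downstream, not the exact covariance
family. The DEM is a planar trend plus scaled noise; streams are
extracted from it by D8 accumulation thresholding, so the channel
network sits in real valleys of the same terrain the predictors are
computed from. Climate surfaces live on a coarse lattice (32 DEM
cells, emulating ~800 m climate products) as intercept +
lapse-rate·elevation + seasonal cosine + smooth noise, then
block-replicated, which is what makes the majority rule meaningful.
Soil fractions come from smoothed composition fields through a softmax,
renormalized to sum exactly 100. Reflectance mixes bare-soil and
vegetation endmember spectra by a vegetation-density field, with a
moisture-driven depression of the shortwave-infrared bands, seeded
sensor noise, and a dry-season vegetation multiplier of 0.6; values
clip to [0, 1].

The ground truth is a logistic suitability surface over standardized
landscape-scale drivers — MRVBF smoothed to a ~200 m footprint (+),
%sand (+), elevation (−), annual precipitation (−), vegetation
density (−) — with default coefficients (2, 2, −1.5, −0.5, −1) and
intercept −3.5, which leaves roughly a fifth of stream units truly
suitable: habitat is a minority, as it is for real habitat
specialists. A strong-signal variant (`STRONG_BETA = (4, 4, −3, −1,
−2)`, `STRONG_BETA0 = −7`) sharpens the niche for recovery
experiments. The drivers are deliberately smooth at the unit scale;
truth that varied within 200 m cells would be unrecoverable by any
unit-level model and would test nothing.

Occurrences are drawn per record with probability proportional to
(mean unit suitability × sampling-bias weight), jittered within their
unit, dated uniformly over the record window and assigned accuracy
from a two-point distribution {30 m: 0.8, 200 m: 0.2} so the 160 m
filter has bite. The default bias concentrates effort around a seeded
focal point. Surveys visit a random unit subset with uniform
night/day counts; detection follows `1 − (1 − 0.4)^visits` in occupied
units (suitability > 0.5), zero otherwise.

What the generator does not emulate: detection-probability structure
beyond that fixed rule, temporal land-cover change between the record
window's ends, atmospheric or sensor physics, realistic hydrographs,
and spatial autocorrelation of record errors. Passing tests therefore
demonstrate that the machinery recovers a known signal under honest
spatial bias and label noise — not that any particular real dataset
would yield a comparable model.

## Numerical choices and problem sizes

Percent slope uses `numpy.gradient`; D8 ties break by fixed neighbor
order; sink filling's epsilon (1e-6 m) is far below any real
elevation precision; the dark-object quantile is an order statistic,
not an interpolated quantile, so the subtraction is always an observed
reflectance; Kaiser retention is strict (> 1); majority ties go to
the smallest value; CV at zero mean is reported as 0. Units dropped
for missing data are logged.

The test-suite and acceptance-script problem sizes are desk-scale by
design: landscapes of 120–480 cells a side (3–12 km), 150–2,000
sample units, 200–1,500 occurrence records, forests of 101–501 trees
with 10 replicates, and 49-permutation significance tests. The
recovery experiment uses the strong-signal truth, uniform effort with
a quarter-extent KDE bandwidth, and ≥300 presence units, and asks the
averaged probabilities to rank truly suitable against unsuitable
units at AUC > 0.9.

## Known limitations

- No reprojection: all inputs must share a projected planar CRS.
- No D-infinity routing, no channel extraction beyond the synthetic
  generator's thresholded D8 network.
- No variable-elimination search over PCs; no occupancy modelling of
  the detection process; no spatially blocked cross-validation.
- The MRVBF implementation is a windowed reformulation of the
  multiresolution cascade, adequate for ordinal use (ranking valley
  bottoms) but not numerically interchangeable with GIS
  implementations of the original.
- Rasters are exchanged as ESRI ASCII grids and vectors as GeoJSON;
  no GeoTIFF/Shapefile I/O.
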