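# Methods

## The modelling problem

`shaderange` estimates where a focal crop (cocoa) and its candidate
shade-tree species find suitable habitat, now and under future climate, from
presence-only occurrence records and gridded environmental predictors. The
pipeline is the standard ensemble species-distribution-modelling (SDM)
workflow used for climate-vulnerability assessments of West African cocoa
agroforestry: occurrence cleaning, background (pseudo-absence) sampling,
collinearity-driven predictor selection, a four-algorithm consensus model,
scenario projection with land-cover-constrained area accounting, and
stacked-SDM richness mapping. Every stage is exercised against *virtual
species* — simulated species with a known environment–suitability
relationship — so correctness is judged against ground truth rather than
plausibility.

## Data model

All rasters live on one north-up WGS84 lon/lat grid (`GridSpec`), default
resolution 2.5 arc-minutes (~4.6 km at the equator). An `EnvStack` holds
named layers sharing one nodata (ocean) mask; each layer is classed
*climatic* (bioclim-style, shifted under scenarios) or *edaphic* (soil,
held constant under scenarios). Occurrence tables are rows of
`(species, lon, lat, year, source)`.

## Occurrence cleaning

Filters only add boolean flags; rows are never deleted, so the audit trail
is complete and re-running the cascade on its own output is a no-op. Order:

1. invalid/incomplete coordinates;
2. off the study grid or on ocean cells (the grid defines the analysis
   universe, so off-extent records are treated as off-land);
3. collected before the climate baseline year (default 1969; "before"
   excludes only strictly earlier years, and undated records are flagged —
   configurable);
4. climatically marginal records: per species and per climatic layer,
   values strictly outside the empirical `[t/2, 1−t/2]` quantile band
   (default tail fraction t = 0.10, i.e. 5% per side), flagged on *any*
   layer. "The outer 10% of the gradient" is ambiguous between one-sided
   and two-sided readings; the two-sided split is symmetric and catches
   both cold-margin plantings and hot-margin errors. The band is computed
   over records passing stages 1–3 (not over what stage 4 itself already
   flagged), which is what makes the cascade idempotent. Species with
   fewer than 20 usable records skip this filter with a warning. Note the
   filter necessarily trims genuine extremes too — on contaminated
   synthetic tables it catches all injected outliers plus ~t of the clean
   tail.
5. fossil or unknown-provenance records, by a configurable source-label
   blacklist (default `{fossil, unknown}`) — the criterion has no machine
   rule, so provenance labels stand in for it;
6. spatial thinning to one record per species per grid cell (tie-break:
   most recent year, then lowest input index — deterministic);
7. a strict minimum sample: a species is modelled only with **more than
   60** retained records (61 kept, 60 dropped).

Not implemented: cross-checking coordinates against administrative
polygons, which needs country boundary data the package does not ship.

## Pseudo-absences

1000 background points per species (default), drawn uniformly **without
replacement over grid cells** that are on land, strictly within 500 km
great-circle distance (haversine, cell centers, R = 6371 km) of at least
one presence, and do not themselves contain a presence. Points are placed
at cell centers, matching the raster resolution of everything downstream.
The buffer is the union of per-presence discs, not a hull. Sampling fails
loudly, reporting the shortfall, if fewer eligible cells exist than points
requested.

## Predictor selection

On the pooled presence + pseudo-absence extraction across all species
(one shared predictor set, not per-species):

1. **Iterative VIF**: VIF_j = 1/(1−R²_j) with R²_j from regressing
   predictor j on all others (with intercept). While any VIF exceeds the
   threshold (default 8), the single worst predictor is dropped and VIFs
   recomputed. Exact collinearity yields VIF = +inf, not an exception.
   Iterative one-at-a-time removal is standard practice; a single-pass
   variant would over-prune.
2. **Pairwise correlation**: while any pair has |Pearson r| above the
   cutoff (default 0.7), the lower-priority member of the worst pair is
   dropped.

Priority stands in for expert ecological ranking. It can be supplied in
config; the default prefers the variable with the lowest mean |r| against
all others (the most independent information). The final set is re-checked
against both thresholds by assertion.

## Ensemble model

Per species, four presence/background classifiers:

| algorithm | implementation | fixed hyperparameters |
|---|---|---|
| GLM | logistic regression on linear + quadratic terms (standardized) | C = 100, lbfgs |
| GAM | additive cubic-spline logistic model (spline basis per predictor, ridge penalty as smoother) | 5 knots, degree 3, constant extrapolation |
| GBM | gradient-boosted trees | 2000 trees, learning rate 0.01, depth 3 |
| RF | random forest | 500 trees |

All stochastic learners are seeded. Constant extrapolation of the GAM
basis keeps projections finite when future climates leave the training
range. Hyperparameters are configurable per run.

**Cross-validation.** Stratified random fourfold assignment (per class,
shuffled indices split as evenly as possible, so no fold is single-class
by construction). Per fold: fit on the other three, score the held-out
fold with AUC (Mann–Whitney, ties at ½) and TSS at the held-out fold's own
max-sensitivity+specificity threshold.

**Weights.** Default (`skill` mode): w_a ∝ max(mean-CV-AUC_a − 0.5, 0),
renormalized to sum 1, so an algorithm at or below chance contributes
nothing. A `raw` mode (w_a ∝ AUC_a) is available for the literal
weighted-average-by-AUC reading; with four decent models raw AUC weights
are nearly uniform, which is why the skill rescaling is the default. If no
algorithm beats chance the fit fails loudly.

**Consensus.** Each algorithm is refitted on all data; ensemble
suitability is the weighted average of member scores (hence always inside
the members' envelope). The binarization threshold is the one maximizing
sensitivity + specificity on the full training data, computed exactly by
scanning the midpoints between adjacent distinct scores (ties resolved to
the midpoint of the whole maximizing score interval, which is stable under
jitter). Predictions are positive at score ≥ threshold. The threshold is
fit once on current conditions and reused for futures.

**Variable importance.** Permutation importance under the species' best
(highest mean CV AUC) algorithm: mean training-AUC drop over permutations
of each column, negatives truncated to zero, rescaled to sum 100%. This is
method-agnostic, unlike tree-native relative influence, so numbers are
comparable across best algorithms; they are not numerically identical to
boosting's internal importance.

## Projection and accounting

Ensembles are applied cellwise to the current stack and each future
GCM stack; per SSP × period the GCM suitability maps are averaged
**cellwise before thresholding** (configurable to per-GCM binarization
with majority vote). Suitable area sums geodesic cell areas
A(row) = R²·Δλ·(sin φ_top − sin φ_bot) by default (a cell-count mode
exists), so equal cell counts at different latitudes give different km² —
deliberate, and guarded by a test. Land cover is held constant across
scenarios; the agroforestry mask restricts suitable area to shrubs,
grassland, cropland and sparse vegetation. Change rasters partition
exactly: gain + stable = future, loss + stable = current.

## Community products

Richness is the cellwise sum of per-species binary maps; hotspots are
cells with richness **strictly greater** than the threshold (default 25
species, per the "more than 25" reading; configurable). The overlap
summary reports, per shade species, the mean focal-crop suitability and
the mean of a chosen layer (default: the layer with the highest pooled
median importance) over that species' suitable cells, plus the
current→future shift. Climatic/edaphic importance sums partition 100% per
species; pooled means/medians are emitted for external group comparisons
(the use/origin-group inference itself is out of scope).

## Synthetic study systems

The generator emulates the *structure* of the real inputs, not their
values:

- **Environmental layers**: Gaussian-kernel-smoothed white noise,
  restandardized to the requested mean/sd, plus an optional latitudinal
  gradient; layers are seeded independently. This gives spatial
  autocorrelation with full seedability; it does not reproduce cross-layer
  correlation structure or topography of real bioclim/soil rasters.
- **Land mask / land cover**: quantile-thresholded smoothed fields —
  contiguous coastlines and patches with near-exact class fractions.
- **Virtual species**: suitability is a product of independent Gaussian
  responses (standard virtual-species practice; kept continuous so truth
  is a surface, not a set), rescaled — with clipping at 1 where
  amplification is needed (solved by bisection) — so mean suitability over
  land equals the prevalence target.
- **Occurrences**: suitability-weighted multinomial over land cells with
  sub-cell jitter (≤0.4 cell), years ≥ 1970; contamination classes (ocean,
  pre-baseline, exact duplicates, climatic extremes) are injected in exact
  numbers and recorded in a hidden `truth` column so each QC filter can be
  scored.
- **Futures**: per-layer linear shifts (factor and offset) on climatic
  layers only; edaphic layers pass through bit-identical.

Because presences are sampled in proportion to suitability and background
uniformly, the achievable presence-vs-background AUC has an information
ceiling of roughly 1 − prevalence/2: a widespread generalist (prevalence
0.3) cannot exceed ~0.86 regardless of model quality, while a specialist
(prevalence ~0.12) supports AUC > 0.9. Recovery benchmarks therefore use a
sharp-niched specialist; this mirrors the real-data situation, where
narrow-ranged species score higher AUCs than widespread ones. Passing
recovery tests shows the machinery identifies the right surface and the
right predictors under these idealized fields; it does not certify
performance on real, spatially biased occurrence data.

## Problem sizes

The bundled demo and the test benchmarks run on 48–120 cell-square grids
with 3 virtual species, 110–500 presences and 200–1000 pseudo-absences —
sizes chosen so a full desk run finishes in seconds to a few minutes while
every contract (counts, distances, identities, recovery) is still binding.
The pipeline itself has no scale assumptions beyond memory: grids are
dense arrays.

## Determinism and provenance

Every stochastic step takes an explicit seed; per-stage (and per-species)
seeds are derived from one master seed by SHA-256 hashing of a label path,
so stages are reproducible independently of one another. The pipeline
manifest records stage, seed and SHA-256 checksum for every artifact;
reruns with the same config are bit-identical (asserted in tests).

## Known limitations

- Rasters are read and written as ESRI ASCII grids with a YAML sidecar;
  GeoTIFF and reprojection are out of scope (inputs must already share one
  lon/lat grid).
- No spatial-block cross-validation; folds are random, which on strongly
  autocorrelated data inflates CV scores.
- No dispersal constraints or land-use-change scenarios; land cover is
  static.
- The marginal-climate filter necessarily flags ~the tail fraction of
  legitimate records; with few records per species it is skipped entirely.
- Model objects live in memory for the duration of a pipeline run; only
  text artifacts (CSV, ASC, JSON) are persisted.
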