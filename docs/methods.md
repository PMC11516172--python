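# Methods

## Scope and data model

`pyroscape` operates on a single pre-aligned analysis grid: every raster
in one run must share shape, cell size, origin and CRS, and the CRS must
be projected (metric).  The package validates alignment but never
resamples — resampling policy changes results silently and belongs
upstream.  Geographic (degree) inputs are rejected because all area
accounting is in km² from the metric cell size.  Point-to-cell mapping
uses half-open intervals `[edge, edge + cell)` on both axes, so a point
exactly on a shared edge belongs to the cell to its right/below; this
makes thinning, extraction and sampling deterministic.

Occurrence records carry one of three seasons (spring, summer, autumn).
Winter is excluded by design: winter fires in the kind of semi-arid
agricultural landscape modelled here are rare and low-intensity.

## Preprocessing

**Thinning** is a greedy sequential scan in input order: a point is kept
iff it is at least `min_distance` from every already-kept point.  Greedy
order-dependence is acknowledged; the scan order is the file order, and a
`shuffle_seed` option permutes it for sensitivity analysis.  Seasons are
thinned independently, since records from different seasons do not
interact statistically.  Defaults: 300 m for satellite fire detections
(the sensor footprint), 1 km for field species records.

**Correlation screening** iterates: find the pair with the largest |r|
above the cutoff, drop the member with the larger mean |r| against all
remaining layers (ties drop the later column), repeat.  This keeps the
more independent covariate and is fully deterministic.  Constant columns
have undefined correlations; they are kept and flagged rather than
silently dropped.  Cutoffs: 0.75 (fire covariates), 0.85 (habitat
covariates).

**Landscape diversity** is Shannon entropy H = −Σ p_k ln p_k of land-use
class proportions in a centered odd-width moving window (default 5×5),
computed by per-class box convolution.  Natural log is used (so H ≤ ln k
for k classes); edge windows are truncated and nodata cells excluded from
the proportions.  A window with no valid cell yields nodata.

**Cross-tabs** count occurrence points per land-use class; percentages
are 100 · frequency / per-season total, reported to two decimals.  Points
on nodata land-use cells go to an explicit `unclassified` row.  One
published reference table for autumn contains a row whose printed
percentage (4.24 for 32 of 132) is inconsistent with its own frequency
column; the package reproduces the arithmetic, not the misprint.

## Two-step pseudo-absence selection

True fire absences are unobservable, so negatives are manufactured in two
steps.  Step one fits three presence-only models on 70 % of the thinned
presences:

* **Envelope** (Bioclim-type): suitable iff every covariate lies within
  the per-variable percentile bounds of the training presences.  Default
  trim 0/100 (strict min/max envelope), 5/95 available.
* **Domain** (Gower-type): similarity to presence *i* is
  1 − mean_v |x_v − p_iv| / range_v with ranges from the training
  presences (zero-range variables excluded and logged); suitable iff the
  maximum similarity reaches θ = 0.95, the conventional cutoff.
* **One-class SVM**: RBF kernel, ν = 0.1, on features standardized to the
  training mean/sd.

Each member's AUC is computed on the held-out 30 % of presences against
an equal-size uniform random background (the standard surrogate when the
negative class is undefined); for binary scores this rank AUC reduces to
(sensitivity + specificity)/2.  Members with AUC > 0.8 are combined by
majority vote with ties voting 1 — risk-conservative: a doubtful cell
shrinks the pseudo-absence pool rather than contaminating it.
Pseudo-absences are drawn uniformly without replacement from the combined
zero region, excluding any cell holding a presence, at 2 × the presence
count, per season.  If no member clears the gate the run aborts with the
member AUCs; manufacturing negatives from models that cannot tell
presences from background would poison everything downstream.

## Classifier suites and ensembling

Two pluggable registries cover the two modelling stages.  `fire6`:
random forest, single classification tree, spline-basis logistic
(adaptive-spline stand-in), gradient-boosted trees, elastic-net
regularized logistic, plain logistic regression.  `sdm8` adds a
GAM-style spline logistic, a single-hidden-layer neural net and a
calibrated kernel SVM.  All learners run with library defaults plus a
fixed seed; no hyperparameter tuning.  Learners that fail to fit are
dropped with a logged warning; fewer than two survivors is an error.

Members are weighted by raw test AUC (normalized to sum 1); the ensemble
probability is the weighted mean, hence always bounded by the member
minimum and maximum at every cell.  `auc-excess` weighting
(max(AUC − 0.5, 0)) is available behind a flag.  Class imbalance (1:2 by
construction) is left unweighted.

**Variable importance** is permutation importance on the test partition
under a random forest: mean AUC drop over 10 permutations per variable,
floored at 0, normalized to sum 1.  When the forest's base test AUC is
below 0.55 there is no skill to attribute and normalizing the flooring
noise would manufacture spurious structure, so the uniform profile 1/p is
reported instead.

## Thresholding and validation

The TSS-maximizing threshold is searched over the midpoints of
consecutive sorted unique scores — the exact optimum under the
`score ≥ threshold` convention lies at one of them, so there is no grid
error.  Ties (within 1e-9, to absorb float noise between algebraically
equal candidates) resolve to the smallest threshold, i.e. the larger
predicted-positive area: conservative when positives are fires or
habitat.  The report carries AUC (rank-based, ties ½), sensitivity,
specificity, TSS, and correct/misclassification = (TP+TN)/N on the test
partition.  All-identical scores are an error (no informative threshold).
Note that a TSS printed alongside sensitivity and specificity is always
their sum minus one here; published species-validation tables sometimes
print TSS values inconsistent with their own rate columns, and this
package reports only the self-consistent definition.

## Seasonal change and overlap

The between-season change surface is |b − a| / max|b − a| with the max
over cells valid in both maps; if the maps are identical the index is
identically 0 by convention.  The index is symmetric in (a, b) and
invariant to positive scaling of the difference field.  Pairs produced by
the pipeline: spring→summer and summer→autumn.

GAP overlap partitions valid cells into at-risk habitat (habitat ∧ fire),
fire-only, habitat-only, and neither; cells nodata in either input are
excluded from all four classes and reported separately, so the four areas
always sum exactly to the valid area.  Class codes 1–4 carry a legend
mirroring the conventional red/blue/green map semantics.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes,
not any particular geography.  Continuous covariates are Gaussian-smoothed
white noise (correlation length 8 cells by default) rescaled to plausible
ranges for a mid-latitude mountainous region: elevation 113–3317 m,
land-surface temperature 289.6–323 K in spring with additive seasonal
shifts (+16 K summer, −5 K autumn), vegetation index −0.17–0.84.  The
road layer is a Euclidean distance transform of generated polylines; the
land-use map slices a second smooth field into classes by quantile and
stamps an agriculture class preferentially at low elevation, so land-use
cross-tabs have structure; the diversity layer is the 5×5 Shannon entropy
of that map.  Default grid: 128×128 cells of 500 m (4096 km²).

True fire risk is `logistic(β0 + Σ β·standardized layer)` per season.
The default coefficients (intercept −17; elevation −4, distance-to-road
−6, LST +5, NDVI +3, diversity −1.5, heat-load +1.5) put the landscape in
a strongly saturated regime: the high-risk region covers roughly 3 % of
cells and risk is near zero elsewhere.  This mirrors how satellite
active-fire detections behave in agriculture-dominated mountain
landscapes — fires hug roads and warm cultivated lowlands almost
deterministically, which is what the high published discrimination of
such models (AUC ≳ 0.9 for presence-only members against background)
implies about the real data.  With diffuse risk surfaces the two-step
procedure is *structurally* unable to pass its own AUC > 0.8 gate: even a
perfect binary classifier's rank AUC is capped at (1 + maxTSS)/2 of the
generating surface, which sits below 0.8 unless occurrence is strongly
concentrated.  The saturated default is therefore part of the study
conditions, not a tuning knob.  Presences are drawn without replacement
with probability proportional to risk and placed at cell centers
(sub-cell jitter off, keeping thinning tests exact); a with-replacement
mode exists purely for frequency tests.

Two synthetic focal species come with habitat-suitability surfaces on the
spring covariates (habitat is modelled season-stable): a highland
ungulate (elevation +3.5, road distance +2 — avoids roads) and a lowland
carnivore (elevation −2.5, road distance −1.5, diversity +1.5 — tracks
human-modified terrain).  Their contrast reproduces the qualitative
pattern that synanthropic species lose far more habitat to fire risk than
highland specialists.

What the generator does **not** emulate: anisotropic terrain, spatially
structured sampling bias, fire spread/contagion, inter-annual weather,
sensor artifacts, or real land-use geometry.  Passing tests on synthetic
data therefore demonstrates that the pipeline recovers known structure
under its own assumptions — not that real-world maps would reach the same
accuracy.

## Numerical and reproducibility choices

* All stage seeds derive from one base seed via SHA-256
  (`derive_seed(base, *tags)`), each below 2³¹, so every run is
  reproducible and stages are independently re-runnable.
* GeoTIFF round-trips preserve dtype (int32 for categorical, the input
  float dtype for continuous); nodata is encoded with the GDAL nodata tag
  and masked on read.
* Box-convolution entropies clamp tiny negative float noise to 0.
* `run_all` writes a manifest (config, seeds, per-stage record counts,
  member AUCs, SHA-256 of every output); reruns with the same config are
  bit-identical, which the test suite asserts.
* Problem sizes in the shipped study (128×128 grid, 300 fire presences
  and 300 species presences per run, 20-seed recovery sweeps) were chosen
  to exercise every stage with stable statistics while staying desk-scale.

## Known limitations

* Greedy thinning is order-dependent by design; maximum-cardinality
  thinning is NP-hard and not attempted.
* AUC evaluation of presence-only members against random background is a
  surrogate with known optimism when presences cover little of the
  landscape.
* The pseudo-absence construction makes downstream validation metrics
  optimistic relative to true prospective skill (negatives are sampled
  from the region the presence-only stage already called no-risk); the
  reported AUCs near 1.0 on synthetic data reflect that construction.
* Habitat models assume season-stable suitability; species with seasonal
  range shifts would need per-season fits.
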