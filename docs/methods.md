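# Methods

This note documents the models implemented in `geomaxent`, the choices made
where the methods literature leaves the design open, what the synthetic test
bed does and does not emulate, and the numerical details that determine the
package's behaviour on edge cases.

## 1. Grids, occurrences, and conventions

All rasters are north-up, row-major, cell-center registered grids in
geographic degrees with square cells, matching the ESRI ASCII / MaxEnt
conventions. The extent is half-open, `[x_ll, x_ll + n_cols·c) ×
[y_ll, y_ll + n_rows·c)`. A point on a shared cell boundary belongs to the
cell east/south of it; the southern and western extent edges (the closed
sides) belong to the last row / first column. Nodata is NaN internally and a
sentinel (default −9999) on disk; a sample is invalid if **any** layer is
nodata at its cell, mirroring how presence/background modelling drops
incomplete cells. Occurrence points falling outside the extent or on nodata
are dropped with a logged count (the source workflows do not document this
case; dropping with a log is the conservative choice).

ESRI ASCII files are written with 17-significant-digit formatting so a
write/read cycle reproduces every finite value and the grid geometry
bit-exactly. GeoTIFF ingestion is out of scope; `.asc` is the canonical,
diffable format.

## 2. Factor detector

The q-statistic uses population (divisor-N) variances, so q = 1 exactly when
every stratum is internally constant — the form the defining equation
implies. SST = 0 (constant response) raises an explicit error rather than
returning NaN.

Stratification: Jenks natural breaks, computed by Fisher's dynamic program
on the distinct sorted values weighted by multiplicity. Working on distinct
values guarantees tied observations share a stratum, and the optimum over
multiplicity-weighted distinct values equals the optimum over raw values
among partitions that do not split ties. Breaks are reported as class
minima; `stratify` assigns `1 + #{breaks ≤ v}` (lower-closed classes). The
number of classes defaults to L = 5.

Response construction: a regular fishnet at a given spacing in km
(111.32 km/degree; longitude scaled by the cosine of the grid's mean
latitude) clipped to valid cells; the response is 1 where at least one
occurrence falls in the half-open fishnet cell (a count response is
available). Default spacing 10 km.

Significance: a permutation test, p = (1 + #{q* ≥ q}) / (B + 1), permuting
the response against the stratum labels. The original geodetector software
uses a noncentral-F approximation; the permutation test is assumption-free
and exact up to Monte Carlo error, which matters at fishnet sample sizes of
a few thousand with a rare binary response. Screening retains variables with
q strictly greater than 0.1.

The pipeline's default screening additionally reconciles the q threshold
with a single-variable jackknife ranking (union with the top half of
variables by with-only training gain), reflecting how combined
geodetector-plus-jackknife screenings are used in practice; set
`geodetector.reconcile: q_only` to disable.

## 3. Maximum-entropy model

Features: linear, quadratic, pairwise-product, hinge (forward
`clip((x−k)/(max−k), 0, 1)` and reverse), and threshold (`x > k`) classes;
hinge/threshold knots at K equispaced interior quantiles of the training
values per variable (default K = 50 per direction). All features are
min-max normalised to [0, 1] on the training sample (presences + background)
so the L1 penalty acts on one scale; features constant on the training
sample are dropped.

Penalty: β_j = base(class, m) · sd_presence(f_j) / √m, with the published
class-default schedules base interpolated in the presence count m
(linear/quadratic/product: 1.0 → 0.2 → 0.05 at m = 10/30/100; hinge 0.5;
threshold 2.0 → 1.0 at m = 0/100), floored at 0.5/√m (hinge) and 1.0/√m
(threshold) so near-constant ramp features cannot escape regularization.
The global multiplier RM scales all β_j; the study configuration is RM = 1
with feature classes LQHPT.

Optimizer: cyclic coordinate descent. Each coordinate takes a proximal
Newton step — gradient g_j = presence mean − model expectation, curvature
h_j = model variance of the feature — soft-thresholded at RM·β_j/h_j, then a
halving line search guarantees the penalized objective never decreases.
After each sweep the full KKT violation is evaluated; iteration stops when
it drops below `tol` (default 1e-5) or at `max_iter` (default 500) sweeps.
Sweeps after the first visit only the active set (nonzero weights plus
current KKT violators), the standard L1 acceleration; this changes nothing
about the solution, only the cost. The KKT certificate — every feature's
expectation within RM·β_j of its presence mean — is the central correctness
oracle and is asserted in the tests.

Outputs: raw r(x) = exp(λ·f(x))/Z with Z the partition sum over the training
background (so raw sums to 1 over background); logistic r·e^H/(1 + r·e^H)
and cloglog 1 − exp(−r·e^H), with H the entropy of the fitted background
distribution. Cloglog is the default, matching the convention of recent
MaxEnt versions; the classification thresholds (below) are
transform-dependent, so the transform is always recorded on the map.
Projection clamps each variable to its training range by default. Duplicate
presences within one cell are collapsed. Background is a uniform
without-replacement sample of valid cells, default 10,000, capped at the
valid-cell count with a log notice.

Hyperparameter sweep: `tune` fits every combination of RM ∈ {0.5, 1, …, 4}
and FC ∈ {L, LQ, H, LQH, LQHP, LQHPT} on one fixed seeded split and reports
the ranking; it deliberately selects nothing automatically.

## 4. Evaluation

AUC is the Mann-Whitney probability P(presence score > background score)
plus half the tie probability, computed from midranks — invariant to
monotone transforms of the scores, so raw/logistic/cloglog give identical
values. The headline evaluation is a single seeded 75/25 split (test size =
round-half-up of n/4); 10-fold cross-validation is available (`cross_validate`)
since both protocols appear in this literature and a single split is the
more reproducible default.

Percent contribution accumulates each coordinate step's positive penalized-
gain increment to the updated feature's source variable(s) (products split
equally) and normalises to 100. Permutation importance permutes one raw
variable column jointly across presence + background rows, re-evaluates the
features, and reports the normalised training-AUC drop (negative drops
floored at zero). The two measures answer different questions (path-
dependent credit vs. post-hoc reliance) and are deliberately kept distinct.

Jackknife: refit with each variable alone and each variable excluded
(same feature classes); report regularized training gains beside the
full-model gain. Response curves are marginal — one variable sweeps its
training range, the others sit at their background means; `optimal_range`
extracts the maximal intervals with prediction ≥ a threshold (default 0.6)
and the argmax. For a rare species a marginal curve can stay below 0.6
everywhere (the other variables sit at typical, unfavourable values); the
argmax is still informative and is the quantity checked against the
synthetic truth.

## 5. Spatial analysis

Classification bins: class 0 iff p < 0.1, 1 iff 0.1 ≤ p < 0.3, 2 iff
0.3 ≤ p < 0.6, 3 iff p ≥ 0.6 (lower-closed). Cell areas are spherical:
R²·Δλ·(sin φ_top − sin φ_bot), R = 6371 km; the error against an ellipsoid
is far below the 2-decimal rounding of reported areas (10⁴ km²). Binary
range change defaults to "any suitable class" (min_class = 1) and is
deliberately configurable: the reporting conventions in this literature do
not always state the reclassification cut, and published stable+loss totals
do not always match the current suitable area, so the cut is exposed rather
than guessed. Gain/loss/unchanged satisfy exact cell-level identities
(unchanged + loss = current; unchanged + gain = future). Centroids are
area-weighted means of suitable cell centers over the binary mask (not
suitability-weighted — the convention when the upstream tools operate on
reclassified binary maps); shift distances use the haversine on R = 6371 km.

MESS: per variable, with f the percent of reference values strictly below
the cell value: S = 100(v−min)/(max−min) if f = 0; 2f if f ≤ 50;
2(100−f) if 50 < f < 100; 100(max−v)/(max−min) if f = 100; the cell score is
the minimum over variables, with the minimising variable recorded. Ties in
the percentile resolve toward smaller f (strict "<"). S = 100 only at the
multivariate reference median; S < 0 exactly where some variable leaves the
reference range. A constant reference variable is an error. The pipeline's
reference sample is the current-period values at the occurrence points.

## 6. The synthetic test bed

The generator emulates the ingredients of a climate-envelope study of a
sharply climate-determined invader:

- **Fields.** Two latent climate axes organise the signal variables: a
  temperature axis (latitudinal gradient + kernel-smoothed noise; poleward =
  colder) and a precipitation axis (weaker gradient, weight 0.7 — the warm
  south is also the wet south). Each temp/precip layer is
  loading·axis + √(1−loading²)·own-noise (loading 0.85, the last precip
  layer negative, emulating wet/dry-season anticorrelation); noise layers
  are independent smoothed fields. This mirrors the strong mutual
  correlation of real bioclim covariates, which is what makes several
  variables individually informative in real screenings. All fields are
  standardized, so coefficients and the warming offset are in field
  standard deviations.
- **Truth.** Suitability = logistic(β₀ + Σβx + Σγx²) with defaults
  temp1 (6, −8) (a band niche with interior optimum at 0.375 sd),
  temp2 (5, 0), precip1 (4, 0), precip2 (−4, 0), intercept −7: prevalence
  ≈ 9% and a suitability-ceiling AUC ≈ 0.93, i.e. a rare, strongly
  determined species like the real study systems this workflow targets.
- **Occurrences.** n distinct cells (default 200) drawn without replacement
  with probability ∝ suitability, placed at cell centers — consistent with
  the one-record-per-cell deduplication downstream.
- **Futures.** Additive offset on temp layers, multiplicative factor on
  precip layers (defaults +0.5 sd, ×0.9). Because layers are standardized,
  the precip factor scales anomalies, not absolute rainfall.

Default grid 60×80 at 0.05°, small enough that the full suite (including a
50-replicate recovery study) runs in about a minute.

What the test bed does **not** emulate: real bioclim identity constraints
(e.g. temperature range = max − min), coastline/nodata geometry, spatial
sampling bias in occurrences, and observation error. Passing recovery tests
therefore demonstrate that the estimators recover a known truth under clean
conditions — not that any particular real dataset is free of bias.

## 7. Numerical details and limitations

- Jenks DP is exact (verified against exhaustive enumeration for n ≤ 12,
  L ≤ 4) and O(L·n²) in distinct values; screening on fishnets of a few
  thousand points takes well under a second per variable.
- The coordinate-descent fit is deterministic given the feature matrices;
  all stochastic steps (background sampling, splits, permutations,
  occurrence draws) take explicit seeds, and the pipeline derives stage
  seeds from one master seed.
- Permutation p-values are bounded below by 1/(B+1); B defaults to 999
  (199 in the pipeline for speed).
- q is clipped to [0, 1] against floating-point underflow of the variance
  decomposition; the clip is inert on non-degenerate data.
- The one-variable closed form (single binary feature, RM = 0) is matched to
  1e-6, and the KKT certificate to 1e-4, in the tests; looser tolerances on
  the stochastic recovery rates reflect Monte Carlo variation, not model
  error.
- Interaction/risk/ecological detectors, categorical features, bias files,
  CRS reprojection and cartographic output are out of scope.
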