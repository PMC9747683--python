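# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data design and the known limitations of the package. It is
the place where genuinely open design decisions are recorded.

## The presence-background model

The model is a maximum-entropy (Gibbs) density over the background
sample: `q(x) ∝ exp(β·f(x))`, fitted by maximizing the penalized log
gain — the mean presence log-density relative to the background
partition function minus an L1 penalty. This is equivalent to an
infinitely-weighted logistic regression of presences against background
and inherits its main assumption: the background sample characterizes
the available environment, and presences are an unbiased (if
effort-free) sample of occupied environments.

**Features.** Covariates are expanded per feature-class set (any subset
of L, Q, H, P, T). Linear features min-max scale each variable to
[0, 1] using bounds from the combined presence + background sample;
quadratic features are the square of that scaled value (the scaling
constant differs from tools that scale x² independently, but the
per-variable function space is the same — the constant is absorbed by
the coefficient); products multiply two scaled variables; hinge
features are forward/reverse ramps and thresholds are step indicators,
both with knots at empirical background quantiles (default 30 per
direction per variable, configurable — knot placement is a free choice
since reference implementations leave it unspecified). Features
constant over the combined sample are dropped.

**Regularization.** λ_j = RM · β_class(m) · s_j/√m, with β_class
interpolated on the presence count m from the published per-class
tables (linear/quadratic/product: m ∈ {0,10,30,100} → {1, 1, 0.2,
0.05}; threshold: {0,100} → {2, 1}; hinge: constant 0.5) and s_j the
presence-sample standard deviation of feature j floored at the
background s.d./√m. RM is the single tuning knob the grid search
varies. An explicit per-feature λ can be passed directly, which is how
the closed-form test instances are posed.

**Optimization.** Cyclic coordinate descent. Each coordinate takes a
proximal-Newton step (gradient = presence mean minus current model
expectation of the feature; curvature = model variance, floored at
1e-12) followed by soft-thresholding, with a halving line search so the
penalized gain is non-decreasing by construction. The fit stops when a
full sweep improves the gain by less than `tol` (default 1e-5, the
value used throughout the pipeline) or after `max_iter` sweeps (default
1000). An optional `tol_beta` additionally requires the largest
coordinate move of the final sweep to be small; near-flat ridges from
strongly correlated features can satisfy the gain criterion while
coefficients still drift by ~1e-3, so oracle-comparison tests set it to
1e-7. Coefficients exceeding 1e3 in magnitude trigger a "separation"
warning and an early stop.

**Outputs.** `raw` is the density normalized to sum to 1 over the
training background (so the log-likelihoods behind AICc are
well-defined); with H the entropy of that distribution, `cloglog = 1 −
exp(−e^H·raw)` (the default, matching the modern default of the
reference tool) and `logistic = e^H·raw/(1 + e^H·raw)` are monotone
squashes into [0, 1]. Projection clamps each variable to its training
range by default; clamping can be disabled to extrapolate feature
ramps.

**Contributions.** Each coordinate update's gain increment is credited
to the feature's variable (products split 50/50). Percent contributions
clip negative credit at zero and renormalize to 100; when every credit
is zero (an all-zero model) the mass is spread uniformly.

## Evaluation and tuning

AUC is the rank-based (Mann-Whitney) statistic with ties counted one
half. OR10 uses the order-statistic threshold — the
(⌊0.1·n_train⌋+1)-th smallest training presence score — and counts test
scores strictly below it; reference implementations differ between this
convention and interpolated percentiles, so the choice is fixed and
documented here. CBI uses 101 windows of width 0.1 spanning [0, 1]
(common practice; no authoritative parameterization exists) and is the
Spearman correlation of window P/E ratios with window centers over
windows holding background mass. Note a subtlety: because the windows
are fixed intervals of the score axis, CBI is *not* exactly invariant
under monotone transforms of the scores — only the final rank step is.
Its single-draw null distribution is also wide (s.d. ≈ 0.19 at 500
presences — effectively ~10 independent windows), so null behaviour is
asserted on seeded ensembles, not single draws.

AICc is `2k − 2lnL + 2k(k+1)/(n−k−1)` with k the number of nonzero
coefficients and lnL the presence log-likelihood under background-
normalized raw output; combinations with k ≥ n−1 are undefined and
disqualified.

Partitions: seeded 75/25 random split; spatial block (four folds at the
median longitude and latitude, points on a median going west/south);
leave-one-out jackknife for small samples (< 25 presences in the
pipeline default); and bootstrap replicates that train on an
n-with-replacement resample and test out-of-bag. Fold metrics average
with equal weight; folds where a metric is undefined (e.g. CBI on a
single held-out presence) are skipped for that metric. Tuning gates —
test AUC > 0.9, CBI > 0.5, delta.AICc < 2 — then minimum delta.AICc
with tie-breaks by smaller AUC.diff, smaller OR10, smaller RM, fewer
feature classes; if no combination passes the gates the same ordering
applies to all defined-AICc combinations and the relaxation is logged.
On strongly spatially structured data, block-partition transfer can be
genuinely poor (held-out quadrants occupy different parts of
environment space), so gate relaxation is common at desk scale and is
reported, not hidden.

## Geodata conventions

Grids are north-up WGS84 with half-open cells (east/south boundaries
belong to the next cell) so thinning and extraction agree; one record
per 2.5′ analysis-grid cell is kept in thinning (first in input order —
deterministic). Rasters carry nodata as NaN and round-trip through ESRI
ASCII grids with 17-significant-digit headers and 9-digit values
(bit-exact for float32); reconstructed origins are snapped to 1e-9
degrees. Resampling is nearest-neighbour or center-based bilinear, with
any contributing nodata poisoning the destination cell; vegetation and
aspect layers are forced nearest. Paleoclimate temperature layers
stored in tenths of a degree (bio1–bio11 by default) are divided by 10.
Slope/aspect use Horn's 3×3 operator with 111,195 m/degree scaled by
cos(latitude) east-west; aspect is the downhill compass direction with
flat cells flagged −1. All spherical geometry (cell areas, centroid
weights, great-circle distances) uses R = 6371 km. Multi-model
ensembles are cellwise arithmetic means with strict nodata (any missing
member blanks the cell) so ensembles share a common support; the member
stack is sorted cellwise before averaging so the result is independent
of member order at floating-point level.

Range dynamics: suitability classes 0–0.1 / 0.1–0.3 / 0.3–0.5 / 0.5–1
with boundaries belonging to the class above; binary ranges at a fixed
threshold (0.5 for change/centroid analyses, 0.1 for multi-species
stacking); GCM rasters are ensemble-averaged *before* thresholding;
centroids are spherical-area-weighted means of present-cell centers
(adequate at subcontinental extent; no antimeridian handling); refugia
are the cells suitable in both the glacial and current periods.

## Variable screening

Screening needs a contribution table; the pipeline obtains it from a
preliminary all-variable LQ fit at RM = 1. Variables contributing more
than 10% are protected; pairs with |r| ≥ 0.8 (Pearson, computed over
the background sample) are processed in descending |r| with
alphabetical tie-breaks, dropping the lower-contribution unprotected
member; two protected members are both kept with the conflict logged.
"Biological significance" is not computable, so an `always_keep` list
provides the expert escape hatch. Correlations default to the
background cells rather than all cells, matching the model's support.

## Synthetic data

Layers are sums of ~10 seeded Gaussian bumps — smooth, low-frequency
surfaces, not white noise — so hinge features, response curves and
spatial partitions are meaningfully exercised. Cross-layer correlation
is imposed exactly: base fields are column-centered and
QR-orthonormalized over cells, then mixed with the Cholesky factor of
the target correlation matrix. Scales mimic bioclim conventions
(temperature-like mean 20/s.d. 5, precipitation-like mean 60/s.d. 25,
elevation 200–2500 m). The truth model squashes a linear (+ quadratic)
form in standardized layers through 1 − exp(−exp(η)) and rescales to
[0, 1]; presences are drawn with probability proportional to
suitability × cell area and placed at cell centers. Period variants add
deterministic per-layer shifts; GCM variants add seeded smooth noise.

What the generator does *not* emulate: real geography or real
WorldClim marginals, spatially biased collection effort, detection
error, or biotic interactions. Passing tests therefore demonstrate the
correctness of the machinery and its statistical behaviour under the
assumed sampling model — not performance on real occurrence databases.

Default fixture scale is a 100×100 grid of 2.5′ cells, 4–6 layers,
200 presences and 2,000 background cells; the full-pipeline fixtures
use a 50×50 grid with 1,000 background cells and 4 bootstrap
replicates. These sizes keep the complete test suite and the
acceptance script within a few minutes on one CPU while leaving every
statistical check well-powered; they are the package's chosen study
conditions, stated here once and used everywhere.

## Pipeline determinism

Every random draw derives from the master seed through named sub-seeds
(CRC32 of "stage:species" labels, folded below 2³¹), so reruns with the
same config and seed produce byte-identical summary CSVs — asserted by
test. Background sampling is uniform over valid study-area cells with
presences not excluded (reference-tool behaviour), 10,000 cells by
default (reduced in desk-scale configs). The final model is fitted as
bootstrap replicates whose continuous suitability rasters are averaged
before any thresholding.

## Known limitations

No categorical features, bias grids or target-group background; no
MESS/extrapolation-risk surfaces beyond clamping; no reprojection
between CRSs (WGS84 only); raster I/O is ESRI ASCII only; no
patch/connectivity metrics; centroid longitude averaging assumes no
antimeridian crossing. Jackknife-fold CBI values are noisy and often
undefined; with very small samples the tuning gates effectively reduce
to the AICc ordering.
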