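# Methods

This note documents the statistical procedures implemented in
`flyniche`, the choices made where a design was genuinely open, and what
the synthetic experiments do and do not demonstrate.

## Accessible area (M)

The calibration region M answers "where could the species plausibly
have been?" and doubles as the background universe for model fitting —
presence-only density estimation is only meaningful relative to an
explicit availability region.  M is built from three criteria:

- **Altitude band** (metres): cells whose DEM value lies in the
  species' reported altitudinal range.  All band comparisons in the
  package are inclusive at both ends, reading printed ranges such as
  "1,000–2,700 m" as closed intervals.
- **Synanthropy band** on the Human Influence Index (HII, 0–64): let v
  be the HII values at the occurrence cells.  Asynanthropic species
  (avoid humans) keep (0, max v) — only the upper bound is informed by
  the data, the lower bound is the index floor; eusynanthropic species
  keep (min v, 64) by the symmetric argument; hemisynanthropic species
  keep (min v, max v).
- **Dispersal buffer**: all cells whose center lies within the species'
  flight range (default 4.8 km, the minimum known flight range of the
  Calliphoridae family) of any occurrence, by great-circle distance on
  a sphere of radius 6371.0088 km.  Buffers are evaluated per cell
  center against exact point coordinates; no polygon rasterization is
  involved, so the operation is exactly testable.

How the environmental masks and the buffer combine is a genuine
ambiguity; the package defaults to **M = (altitude ∩ HII) ∪ buffer**,
which guarantees every occurrence stays inside its own calibration
region (the fitting stage requires this), and also offers
`env_intersect_buffer` for the strict-intersection reading.  Every
result records which rule was used.

## Occurrence preparation

Spatial thinning is a greedy pass in record order: a record is kept iff
it is farther than `min_distance` km (haversine) from every record
already kept; `min_distance = 0` removes only exact coordinate
duplicates.  The default distance is one cell diagonal of the landscape
grid — the minimal defensible choice, removing same-cell
pseudo-replicates — and is a config setting, since published thinning
distances vary by study.  Thinning is idempotent.

Collinearity filtering computes pairwise Pearson correlations
(population normalization — immaterial to |r| comparisons, fixed for
determinism) over non-nodata cells, optionally restricted to a region.
While any pair exceeds the threshold (default 0.8), the member of the
worst pair with the larger mean absolute correlation against the other
remaining layers is dropped; ties drop the later layer.  The drop-order
heuristic is this package's own pin — the threshold rule alone does not
determine which member of a pair goes.

## Maximum-entropy model

The suitability model is the Gibbs density over background cells

    raw(x) = exp(λ·f(x)) / Z,   Z = Σ_b exp(λ·f(b)),

with features f built per class: linear, quadratic, pairwise products,
threshold steps and forward/reverse hinge ramps, each affinely scaled to
[0, 1] on the background sample.  Knots (default 20 per layer per
direction, configurable) are evenly spaced strictly inside each layer's
background range.

Coefficients minimize the convex objective

    −mean_pres[λ·f] + log Σ_b exp(λ·f(b)) + Σ_j β_j |λ_j|,

whose optimality condition is the soft moment box
|E_model[f_j] − mean_pres[f_j]| ≤ β_j.  The per-feature penalty is

    β_j = RM · base(class, n) · s_j / √n,

with s_j the feature's background standard deviation, n the presence
count, and `base` a per-class table interpolated linearly on n
(linear/quadratic/product: 1.0 at n≤10 → 0.05 at n≥100; threshold: 2.0 →
1.0; hinge: constant 0.5).  The table is this package's documented
default — it follows the shape of the published Maxent defaults
(thresholds penalized hardest, penalties relaxing with sample size) but
exact replication of any particular Maxent release is a non-goal.  RM
multiplies every β linearly.

The solver runs L-BFGS-B on the positive/negative split of λ, which
handles the L1 term exactly and is monotone in the penalized objective.
Stopping couples the configured objective-improvement tolerance
(default 1e-5) with a projected-gradient tolerance of 1e-9; if the
objective stop fires before stationarity is certified, the solver
polishes within the remaining iteration budget (cap 5000).  A fit is
flagged converged when the moment box holds within 1e-6 for every
feature.  Background raw scores sum to one by construction.
Predictions are only defined inside M; there is no clamping and no
extrapolation — callers must mask.

Two variable-importance diagnostics are provided.  The jackknife refits
the model without each layer and with each layer alone and reports the
regularized training gain of each; permutation importance shuffles one
layer's values jointly across presence and background rows and reports
the mean drop in training gain under the fitted coefficients, floored
at zero and normalized to sum to 100%.  Permutation importance is the
package's contribution metric: sequential "percent contribution"
bookkeeping is path-dependent in the coefficient trajectory and is not
reproducible across solvers.

## Tuning and selection

Candidates are the inclusive RM grid (default 0.5–4.0, step 0.5)
crossed with the feature-class sets L, LQ, LQP, LQPT, LQPTH — 40
configurations.  Each is fitted on the full presence set and scored by

    AICc = 2k − 2 lnL + 2k(k+1)/(n − k − 1),

with lnL the presence log-likelihood under the background-renormalized
raw scores, k the number of coefficients with |λ| > 1e-8, and n the
presence count; AICc is flagged undefined when k ≥ n − 1.  This is the
Warren–Seifert convention of the presence-only tuning literature.  The
minimum-ΔAICc candidate wins; ties break by smaller k, then smaller RM,
then feature-class order (all three pins are this package's own).

The selected configuration is refitted in replicates (default 10), each
holding out ⌈0.25·n⌉ presences drawn uniformly without replacement,
independently per replicate under seeded sub-streams.  A
`replicate_type="bootstrap"` variant resamples the training partition
with replacement instead.  The final suitability estimate is the
cellwise median of the replicate maps — median aggregation is
insensitive to a single divergent replicate and permutation-invariant.
The pipeline evaluates this median map against the pooled held-out
presences of all replicates.

## Partial ROC and LTPT

The partial-ROC statistic replaces the false-positive axis with the
fractional predicted area a(t) (proportion of M at or above threshold
t) and restricts the curve to sensitivities s(t) ≥ 1 − E (E = 0.05 by
default).  Thresholds sweep the descending unique prediction values,
binned to at most 1000 classes — the statistic is rank-based, so the
binning only bounds runtime on large rasters.  Per bootstrap replicate
(default 100), ⌈0.5·m⌉ of the m test points are resampled with
replacement; the AUC ratio is the trapezoidal area under s-vs-a on the
restricted region divided by the area under the diagonal s = a on the
same a-interval, and the crossing into the region is interpolated at
exactly s = 1 − E so the restriction does not add discretization bias.
A constant prediction returns ratio 1.0 in every replicate (a constant
map *is* a random classifier) rather than erroring.  The summary
p-value is the fraction of bootstrap ratios ≤ 1.

**Known limitation.** With small resampled test sets the statistic is
slightly biased above 1 even for random predictions: the restricted
region is anchored at the lowest test-point order statistics, and the
k-th smallest of m uniform values sits at k/(m+1) in expectation while
the sensitivity steps at k/m, so the curve's high-sensitivity corner
lies above the diagonal.  At 25 resampled points the mean ratio for a
random prediction is ≈ 1.03 (well within the package's own ±0.1 check),
but the p-value is anticonservative — essentially every bootstrap ratio
exceeds 1.  Significance claims for marginal models (ratios barely
above 1) should therefore lean on the magnitude of the ratio, not on p
alone.

The lower-training-presence threshold at allowable error E sorts the
predicted values at the training presences, drops the lowest ⌊E·n⌋, and
thresholds at the smallest remaining value; the omission (fraction of
presences strictly below the threshold) is therefore ≤ E for any input.
Binarization is inclusive (prediction ≥ threshold is suitable), and
cells outside M are nodata, not unsuitable.

## Synthetic landscapes

The generator emulates the statistical structure the pipeline assumes
rather than any particular climatology: environmental layers are white
noise smoothed with an isotropic Gaussian kernel (length scale in
cells) and affinely rescaled; the DEM spans 0–4000 m and the HII grid
0–64 by the same construction.  When a target pair correlation is
requested, the second field is decorrelated against the first using the
realized sample correlation (empirical Gram–Schmidt) and remixed at the
target weight, so the sample correlation lands on the target up to
float error — an analytically chosen population weight alone can miss a
±0.05 band on small grids, where spatial autocorrelation shrinks the
effective sample size.

Species are sampled at cell centers with probability proportional to
exp(w·env) over the cells satisfying the altitude and HII bands;
duplicate cell draws are collapsed and sampling repeats until the
requested number of distinct cells is reached (museum records are
effectively one per locality), erroring if the eligible region is
exhausted.  Placement at cell centers makes value extraction exact and
every test deterministic.

What passing synthetic tests shows: the estimator recovers a known
log-linear suitability ranking (Spearman ≥ 0.8 at 200 presences, 5
layers, one informative), selection prefers candidates that track the
truth, and every procedural constant behaves as specified.  What it
does not show: robustness to the covariance structure of real
bioclimatic variables (19 strongly and heterogeneously correlated
layers), to spatial sampling bias in museum records, or to positional
error in georeferencing — none of which the generator emulates.

## Problem sizes and determinism

The test suite and the acceptance script run on grids between 20×20 and
100×100 with 60–200 presences and backgrounds up to ~3000 cells — sizes
chosen so the full default tuning grid fits in well under a minute
while every statistical check retains power; the same code paths scale
to the 10,000-cell background cap unchanged.  One master seed spawns
independent sub-streams per species, stage and replicate
(`numpy.random.SeedSequence`), and rerunning any pipeline with the same
config and seed reproduces byte-identical outputs; the run log records
the sub-seeds and output hashes.
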