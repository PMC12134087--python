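# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
study does and does not establish.

## Revisitation detection

A candidate site is a circle of radius `r` (default 250 m) centred on a
trajectory fix; the circle is moved along every fix (or every k-th fix via
`centre_stride` at large problem sizes).  A *visit* is a maximal interval
during which the path is inside the circle.  Entry and exit times are
refined by solving the segment-circle intersection analytically under the
constant-velocity-per-segment assumption; this also catches "dip-ins" where
both neighbouring fixes lie outside the circle but the straight segment
between them passes through it.  Conventions, all deterministic:

* the disc is closed (a fix on the boundary is inside);
* a tangent contact (zero discriminant) is not a crossing;
* a track that starts or ends inside a circle opens or closes its visit at
  the first or last fix time;
* consecutive in-circle intervals separated by **less than**
  `min_time_away` (default 12 h) outside the circle are merged — a return
  after exactly 12 h away counts as a new visit.

`n_visits` counts all maximal visit intervals including the first, so an
unrevisited location has `n_visits = 1`.  Sites are not spatially
deduplicated: one record per fix, as produced by the moving circle.

The circle radius is chosen by the variance-peak rule: per candidate radius
the variance of `n_visits` across a given individual's sites is computed,
per-individual variances are summarised by the median across individuals
(a robust aggregate of a per-individual criterion), and the radius with the
maximal summarised variance wins; ties break to the smaller radius.

## Water filter

All revisitation sites whose centre lies within the water buffer (default
500 m, planar metric buffer) of any permanent-water feature are removed,
because water-point revisits are dominated by drinking rather than
foraging.  Water features are GeoJSON geometries in the same projected CRS.

## Home range and availability

The home range is a union of local convex hulls over the pooled fixes of
all individuals, unioned in ascending area order until the polygon contains
the isopleth fraction of points (default 1, i.e. all points).  Two
neighbour rules are implemented:

* `radius` (default): all neighbours within distance `a` of the root.  The
  default `a` is the maximum observed pairwise distance, under which every
  local hull uses all points and the isopleth-1 polygon equals the global
  convex hull — the parameterisation for a home range that must encompass
  100% of the data.
* `cumulative`: the adaptive rule (neighbours added in order of increasing
  distance while the cumulative distance stays ≤ `a`), which adapts hull
  size to local density and is the useful setting for informative `a`
  values.

Availability is complete spatial randomness: points rejection-sampled
uniformly in the home range minus the buffered water area, each stamped
with an entry time drawn with replacement from the observed visit entry
times so that time-varying covariates can be extracted for them.  The
pooled (all-individuals) range is used because one availability sample is
compared against every sex/season subset; per-individual ranges are
available by calling `alocoh` per individual.

## Covariate extraction and transforms

Static rasters (soil phosphorus ppm, nitrogen g/kg, elevation m) are
sampled at the site centre by nearest cell, no interpolation; missing cells
and out-of-extent points are flagged, never filled.  Dynamic series (EVI
16-day, day land-surface temperature 8-day, precipitation 5-day) use the
last record at or before the visit entry time — the boundary is inclusive
(a record exactly at entry time is used), and extraction never looks into
the future.  For a site-season record with several visits, the per-entry
dynamic values are averaged.

Transforms used in all models:

* distance to water → square root (the available area in a distance band
  grows quadratically with distance);
* slope in degrees (Horn 3×3 finite-difference gradient of elevation, edge
  replication at borders) → `log1p` (many near-flat cells, few steep ones;
  `log1p` rather than `log` keeps 0° finite and interpretable).

Collinearity screen: Pearson correlations on complete rows; for a pair
with |r| strictly above the threshold (default 0.5) the lower-priority
column is dropped (phosphorus outranks nitrogen, so a correlated nitrogen
is the one removed).  Constant columns have undefined correlations; they
are flagged and retained.

## Season segmentation

NDVI is standardised over the whole tracking period (sample-sd convention)
and smoothed with a centred 3-record moving mean.  Within each season-year
(July–June, so a southern-hemisphere November–April wet season never
straddles a year boundary) the wet season is the longest contiguous run of
standardised NDVI above 0, with the run limits interpolated linearly
between records — the two seasonal cut points.  The rest of the year is
dry; wet intervals are closed (boundaries are wet).  A year with no
crossing has no seasonal signal and falls back to calendar seasons
(November 1 – May 1 wet) with a warning.  The threshold, window and rule
are parameters; this is the simplest two-cut-point scheme consistent with
an NDVI-indicated wet season, not a reimplementation of any particular
external tool.

## Revisitation rate

For season type s, the rate at a site is the number of visits entering
during type-s intervals divided by the number of type-s seasonal periods
the individual's tracking span overlaps, counting partial overlap
fractionally (per year, overlap duration with that year's type-s intervals
divided by their total duration).  This rescales counts for unequal
tracking periods.  Site-seasons with zero visits or zero overlap produce no
record.  The rate distribution is right-skewed; the package fits normal,
log-normal, Weibull and gamma families by maximum likelihood (2 parameters
each, location fixed at 0 for the positive families) and ranks them by AIC.
Models use log rate as the response.

## Used-vs-available comparison

With thousands of sites against 10^5 availability points a single
two-sample Kolmogorov test rejects for trivial differences, so the test is
repeated (default 10,000 times) on balanced subsamples of m = 100 used and
100 available values, reporting mean ± SD of D and p and the rejection
fraction.  D is the sup distance between the empirical CDFs evaluated at
all pooled jump points (exact under ties); p is the asymptotic Kolmogorov
tail at effective size mn/(m+n).  Subsampling is without replacement within
an iteration; a bootstrap (with replacement) flavour is a flag.

Calibration caveat: for m = n = 100 the statistic is lattice-valued
(multiples of 1/100), so the p-values are discrete and cannot be uniform on
(0,1) no matter how well calibrated; a literal KS test of the p-values
against U(0,1) always rejects on discreteness alone.  The package therefore
provides the exact equal-n null distribution of D (classical reflection
formula) and a randomised probability-integral transform
(`selection_stats.null_pit`); the transformed values are exactly U(0,1)
under the null, making a KS uniformity test of them a valid calibration
check.  The plain asymptotic p at this subsample size is mildly
conservative (null rejection ≈ 4% at nominal 5%).

## Mixed models and selection

The response is log revisitation rate; predictors are the scaled (zero
mean, unit sample variance, within the modelled subset) covariates with
quadratic terms built from the scaled values (scale, then square), and a
random intercept per individual.  Models are fitted separately per sex ×
season stratum; stratum is a configuration axis, not a model term.
Precipitation participates in the exploratory binned regressions but is not
a mixed-model candidate.

The fitter is an exact profiled-likelihood random-intercept implementation:
for a fixed variance ratio λ = σ²_α/σ²_ε the GLS estimate, profiled σ²_ε
and the (restricted) log-likelihood are closed-form via the
Sherman–Morrison identity per group, leaving a 1-D optimisation over
log λ.  ML is used during selection so AIC is comparable across fixed
structures (k = p + 2 parameters); the chosen model is refit by REML for
reported variance components.  The test suite verifies agreement with a
general-purpose mixed-model implementation to ~1e-5 in log-likelihood.

Backward elimination removes, at each step, the removable term whose
removal gives the lowest AIC, respecting marginality (a quadratic before
its linear term, an interaction before its main effects), and descends all
the way to the intercept-only model rather than stopping at the first
local minimum — otherwise a noise quadratic that happens to look
informative can trap its main effect in the model and hide the more
parsimonious candidates from the 2-ΔAIC rule.  Among every model fitted
during the search with AIC within 2 of the best, the one with the fewest
fixed-effect terms is chosen (ties break lexicographically on the sorted
term names).  Marginal and conditional R² follow the variance-components
formulation: Rm² = σ²_f/(σ²_f+σ²_α+σ²_ε) and Rc² = (σ²_f+σ²_α)/(…), with
σ²_f the population variance of the fixed-effect linear predictor; they are
reported as mean ± SD over stratified resamples (default 100 at desk scale;
a config knob) of the covariate gradients.

Stratified resampling cuts each focal covariate's range into equal-width
strata (default 10) and draws the same number of rows from every non-empty
stratum (without replacement where possible), then deduplicates the union
across focal variables — flattening the data density along the gradient so
the sparse extremes are not swamped.  The per-stratum draw defaults to the
smallest non-empty stratum count.

Interactions are only considered from an allow-list (default: EVI×slope,
water×slope, EVI×phosphorus, water×phosphorus) added to the selected base
model when both main effects are present, followed by a second backward
pass.

Binned exploratory regressions: each covariate's range is cut into 1000
equal bins, the mean log rate per non-empty bin is regressed (OLS) on the
bin centre and its square.  The final bin is right-closed; empty bins are
omitted.

## Synthetic study

The generator emulates the study system so every stage is testable without
field data: smooth covariate fields (Gaussian-filtered white noise,
smoothing length 1.2 km), nitrogen constructed as ρ·z(P)+√(1−ρ²)·noise with
ρ = 0.8, seasonal EVI/NDVI/temperature/precipitation series with a
mid-January greenness peak, one sinuous river plus Poisson waterholes, and
hourly multi-month trajectories of foragers that travel between discrete
hotspot patches and dwell at them.

Hotspots are patches of radius 250 m with centres at least 600 m apart
(overlapping patches would double-count at small radii), sampled with
probability ∝ exp(η) where η is the planted log-attractiveness — a linear +
quadratic form in standardised transformed covariates, by default concave
in phosphorus (β = 1.0, −1.2) and concave in √distance-to-water
(β = 0.6, −1.0) — plus an independent per-patch quality jitter
(log-scale SD 1.0) representing unmeasured site quality.  Visit weights are
∝ exp(η).  Movement alternates gamma-dwell bouts (mean 20 h) at a
uniform-in-disc anchor within the patch (tight AR(1) wander around the
anchor, so each bout works one part of the patch) with biased correlated
random-walk travel (gamma steps, mean 1.2 km/h); the next patch is chosen
∝ weight × exp(−distance/350 m), a strong locality kernel.

These scales are deliberate: bout anchors spread over the 250 m patch make
100 m circles undersample visits; patch spacing ≥ 600 m keeps 250 m circles
patch-specific; and local back-and-forth between adjacent patches means
500 m circles rarely stay empty for 12 h, merging their visits — so the
across-site variance of visit counts peaks at the 200–300 m scale, which is
what the radius-selection rule should find.  The per-patch quality jitter
keeps neighbouring patches from being perfectly alike (smooth fields would
otherwise make the 500 m scale as variable as the 250 m one).

What the generator does **not** emulate: behavioural memory dynamics,
social structure, sex-specific movement rules, GPS error, fix dropout,
cloud/QA artefacts in the satellite series, and any calibration to real
animal-movement statistics.  Passing the recovery tests shows the pipeline detects
what it is supposed to detect under its own assumptions (constant-velocity
interpolation, point extraction, log-linear attraction); it does not
validate those assumptions against real movement data.

## Problem sizes and numerics

Desk-scale defaults used by the test suite and the acceptance script: 5
individuals (3 bulls, 2 cows) × 1 year of hourly fixes on an 8 × 8 km
domain with 80 patches; the moving circle is evaluated on every 4th–8th fix
(`centre_stride`) in the large replicated experiments and on every fix in
the unit tests; 100-replicate (rather than 10,000) R² resampling.  All
randomness flows from a single integer seed through `numpy` seed sequences;
reruns are bit-identical.  Numerical tie-breaks are documented where they
occur: argmax ties to the smaller radius, AIC ties to the lexicographically
smaller term set, boundary fixes inside the disc, record-at-entry-time
included.  The λ optimisation is bounded on log λ ∈ [−12, 12] with the
λ → 0 boundary checked explicitly.

## Known limitations

* Constant-velocity interpolation between hourly fixes understates
  tortuosity; crossing times are approximations.
* Point (centre) covariate extraction; a circle-mean footprint is not
  implemented.
* The season rule assumes one wet season per year.
* The exact small-sample KS distribution is used only for calibration
  checks, not for the reported p-values (which are asymptotic, as stated).
* No spatial autocorrelation structure in the mixed models; random
  intercepts only.
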