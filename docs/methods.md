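# Methods

This note documents the statistical procedures, the synthetic-data
generator, and the numerical and design choices behind them.

## Diapause scoring

A reared larva either pupates (direct development) or overwinters as a
larva (diapause). The binary outcome is read off the recorded pupation
day: direct development iff pupation happened *strictly before* day 55 in
the 16 °C treatments or day 33 in the 22 °C treatments; pupation on the
threshold day, or no pupation, scores as diapause. Day counting starts at
the experiment start (larvae enter at age 0–2 days; the offset is far
smaller than the gap between the developmental modes). Two alternative
threshold sets, `early` (49/29) and `late` (61/37), exist for sensitivity
checks; because diapause requires pupation on/after the threshold, raising
the threshold can only reclassify individuals towards direct development.
Individuals that died are removed before scoring and before every model;
the mortality fraction is reported alongside.

Temperature is carried as a two-level label (`cold` = 16 °C, `warm` =
22 °C). Measured cabinet temperatures deviate from nominal by well under a
degree and are treated as metadata.

## The reaction-norm model

The diapause probability of individual *i* in family *f* and population
*p* is modelled on the logit scale as

    η_i = β0_p + β1·D_i + β_T·1[warm] (+ interactions) + u_f,
    u_f ~ N(0, σ_f²),

with daylength D in hours. Populations enter as separate intercepts with
no global intercept, so the critical daylength of population *p* is simply
β0_p/(−β1) — no contrast arithmetic. The candidate interactions are
daylength × population (population-specific slopes, coded as deviations
from a reference population) and temperature × population. Daylength ×
temperature is excluded by construction: with few daylength levels its
signature cannot be separated from the temperature main effect.

**Likelihood.** The family intercept is integrated out by adaptive
Gauss–Hermite quadrature: per family the integrand is re-centred on its
posterior mode (found by damped Newton iterations on the concave
per-family objective, to gradient < 1e-12) and re-scaled by its curvature
before the 15-node Hermite rule is applied. With σ_f = 0 the code takes
the exact Bernoulli branch, so the boundary value is not subject to
quadrature error. Fifteen nodes reproduce a 1e5-point brute-force
integral to better than 1e-6 on single-observation families (tested), and
the full fit matches `lme4::glmer(nAGQ = 15)` to ~1e-4 on coefficients and
1e-6 on the log-likelihood (tested against R as an independent oracle).

**Optimisation.** Quasi-Newton (L-BFGS-B) over (β, log σ_f) from a null
start: β from a plain IRLS logistic fit, σ_f = 0.1. log σ_f is bounded in
[log 1e-8, log 50]; β in ±2000 (intercepts scale as |slope| × CDL, so the
box must sit far beyond the |β1| > 50 separation cap). If freeing the
variance improves the plain-logistic likelihood by less than 1e-7 the fit
is snapped to the σ_f = 0 boundary — this makes "variance estimated at
zero" an exact statement rather than a tolerance judgement. The outer
gradient is obtained by central finite differences (the inner Newton makes
the objective smooth to ~1e-12); the convergence flag requires a
finite-difference gradient sup-norm below 1e-3 and a finite observed-
information covariance. Fixed-effect covariance is the inverse numeric
observed information over β at the optimum, with σ_f held at its estimate.

**Separation.** A population is flagged when daylength perfectly separates
its outcomes (all diapausers at strictly shorter days than all direct
developers, or only one outcome class present) — the exact combinatorial
condition — and additionally whenever a fitted slope exceeds 50 in
magnitude. Flagged fits are returned for inspection, but critical-daylength
extraction refuses them.

**Inference.** Type-II likelihood-ratio tests: each main effect is tested
against the model containing all other terms except interactions involving
it; each interaction against the full model minus itself; χ² = 2Δℓ, df =
the difference in coefficient count. Pairwise population contrasts come
from the additive model (the intercept difference is then the logit
difference at any daylength); the familywise-adjusted p is
P(max_j |Z_j| ≥ |z_i|) for a zero-mean multivariate normal with the
contrasts' correlation matrix, estimated by 1e5 Monte-Carlo draws with a
fixed seed (adjusted p is floored at the raw p so the Monte-Carlo error
cannot invert the ordering). The family variance is tested by LRT between
the free and σ_f = 0 fits with the p-value halved, because the null lies
on the parameter-space boundary; a zero variance estimate gives adjusted
p = 0.50 exactly.

## Critical daylengths and the bootstrap

CDLs are estimated from per-temperature models containing only daylength
and population. Uncertainty comes from a nonparametric bootstrap, B = 1000
by default: individuals are resampled with replacement within each
population × daylength cell (preserving the design margins), each resample
is refit as a *fixed-effects* logistic model, and the 2.5/97.5 percentiles
of the replicate CDLs form the interval; the replicate variance is the
estimate's sampling variance for the meta-regression. The family term is
dropped in replicates because its variance is estimated at ~0 in these
designs and refitting 1000 GLMMs would buy nothing; a family-level
resampling scheme (`scheme="families"`) is available for designs where the
family variance matters. Replicates with separation or a non-negative
slope are dropped and counted; more than 10% failures aborts with an
error, since the percentile interval would then be biased by selective
deletion. Coverage of the 95% interval is 89–99% across 200 simulated
experiments at 15 individuals per cell (tested).

## Latitudinal cline (meta-regression)

CDL estimates θ_i with known sampling variances v_i (the bootstrap
variances) are modelled as θ_i = α + γx_i + δ_i + ε_i with ε_i ~ N(0, v_i)
and δ_i ~ N(0, τ²). τ² is estimated by REML — profiled to 1e-10 by bounded
scalar minimisation with an explicit boundary comparison at τ² = 0 — and
(α, γ) by weighted least squares with weights 1/(v_i + τ²). The
implementation matches `metafor::rma.uni(method = "REML")` to 1e-6
(tested). The pseudo-R² is (τ²_null − τ²)/τ²_null against the
intercept-only REML fit, floored at 0 and reported as not-available when
τ²_null = 0. When all v_i + τ² vanish (exact collinearity) the weights
degenerate to uniform and the fit is the OLS line with zero residuals.

Two presentation variants are produced: absolute CDL against latitude, and
the difference from the southernmost reference population within each
experiment (variances added as for independent estimates, reference rows
removed), which removes the between-experiment offset. The correlation
induced by the two populations shared between experiments is ignored —
estimates are treated as independent. Confidence bands are pointwise
delta-method bands, fit ± 1.96·SE(α̂ + γ̂x).

## Range-expansion analysis

Coordinates are projected with a spherical transverse Mercator (R =
6 371 000 m, scale 1, central meridian 15 °E, origin at the equator) — the
published analysis used a GIS grid whose CRS is not stated; at the tested
effect sizes (fronts moving 100 km between periods) results are invariant
to small CRS differences, and the projection is configurable. Grid cells
are half-open 20 × 20 km squares (a point on a lower/left edge belongs to
that cell). Per square and period the analysis counts records, distinct
species, and target-species occurrences; squares with at least 100 records
in *every* period are well-recorded (species accumulation saturates around
100 records per square, which the saturation table lets one verify).

Margin selection takes the k = 10 most extreme target-occupied squares per
period: by centroid latitude (descending; ties broken west-first, then by
indices, for reproducibility) within the eastern (centroid ≥ 14.31 °E) or
western region, or by ln distance from the square centroid to the nearest
coastline (exact point-to-segment distance over the polyline parts — a
strict superset of vertex-hub distance, equivalent for a dense polyline).
Squares rather than raw observations are used throughout, and the region
split applies to square centroids. The first period uses all target
squares, later periods only well-recorded ones: historical recording is
too sparse for the filter, and applying it only to the modern periods
biases against detecting a shift, making the test conservative. Shifts are
tested by one-way fixed-effects ANOVA on the metric with Tukey HSD
pairwise period comparisons; an all-constant input is reported as F = 0,
p = 1 rather than 0/0.

## Synthetic data

The rearing generator draws one Normal(0, σ_f²) offset per family, shared
across treatments (split-brood design: offspring of each female are
divided equally among treatments), Bernoulli outcomes from the logistic
truth, rounded-Normal pupation days truncated strictly below the scoring
threshold for non-diapausers, and independent mortality that erases the
outcome. Families are balanced (the real experiments' family imbalance is
not reported at a usable resolution; the counts are adjustable). Default
conditions mirror the two experiments: eastern cline — 4 populations
(CDLs 15.85–16.5 h), 4 daylengths 14.5–17.5 h × 2 temperatures, 10
families × 2 offspring per treatment (n per cell = 20, inside the reported
8–38 range), mortality 5.3%; western cline — 5 populations (16.0–16.7 h,
slightly longer than the east, as observed), 5 daylengths including
16.0 h, 16 °C only, mortality 11.8%. Slope −2 logit/h, warm offset −1
logit and family SD 0 (the experiments estimated the family variance at
zero) are round-number choices consistent with the reported reaction-norm
shapes, not fitted quantities.

The occurrence generator is Poisson throughout: background records with a
log-normal spatial effort field (median 80 records/square, log-SD 1)
scaled per period by (0.8, 2.5, 4.0) — sparse historical recording, dense
modern recording, so a realistic minority of squares pass the
well-recorded filter — and target records at rate 3 per occupied square
in squares south of a front that advances 100 km per period. What it does
**not** emulate: non-Poisson clumping of recording effort (observer
bursts), misidentifications, spatial autocorrelation of occupancy beyond
the front, inland-vs-coastal colonisation dynamics (the front is flat in
y, so the inland-distance test has no built-in signal), and any climate
dependence. Passing tests therefore demonstrate that the pipeline recovers
the truth *under its own assumptions* — effort control, margin statistics
and shift tests behave correctly — not that the real data are free of the
biases the filter is meant to contain.

## Problem sizes

Default test and driver sizes are chosen to exercise the study's own
scale: ~600/440 survivors per experiment (the real experiments' order of
magnitude), B = 500–1000 bootstrap replicates, 200-replicate coverage and
calibration simulations, 100-seed range-expansion detection runs, and a
700-square occurrence grid with ~650k records. The bootstrap refits run on
cell-aggregated sufficient statistics, which is what makes the coverage
experiments cheap.

## Known limitations

* The bootstrap definition (individual resampling within cells,
  fixed-effects refits, percentile intervals) is this package's own
  precise specification of a procedure that is often left under-specified;
  alternatives (family resampling) are exposed but not the default.
* The meta-regression ignores the covariance between experiments induced
  by shared populations, and REML is fixed as the τ² estimator.
* Separation handling drops bootstrap replicates rather than truncating
  them; with very sparse cells this aborts (by design) rather than
  reporting an interval.
* The projection is spherical, not ellipsoidal; adequate for 20-km
  gridding (sub-kilometre error at these latitudes), not for geodesy.
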