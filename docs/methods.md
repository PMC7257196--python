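# Methods

This note records the statistical model the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## The two-stage model

Audit items are binary responses Y(s) at projected planar locations s
(meters; the package never reprojects — inputs are assumed already in an
equidistant projection so Euclidean distance is honest). Stage one is a
maximum-likelihood logistic regression of Y on a centered cubic polynomial
of the coordinates, optionally plus rater dummy codes (raters 1..R−1
against the last level as reference). Stage two treats the deviance
residuals

ε_i = sign(y_i − p̂_i) · sqrt(−2 [ y_i ln p̂_i + (1−y_i) ln(1−p̂_i) ])

as a spatial field: an empirical semivariogram is estimated, a nested
theoretical model is fit by weighted least squares, held-out residuals are
predicted by local ordinary Kriging, back-transformed to the probability
scale and added to the scored trend, ŷ = clip(p̂ + r*, 0, 1). Prediction
quality is measured by RMSPE against the 0/1 response and by ROC AUC
(concordance with ties at ½), labeled None / less than Acceptable /
Acceptable / Excellent / Outstanding at 0.5 / <0.7 / 0.7 / 0.8 / 0.9.

### Trend details

- Seven spatial terms {x, y, x², y², xy, x³, y³} by default. A full cubic
  has nine non-intercept terms; the seven-term set matches the convention
  of indexing the spatial coefficients β₁–β₇, and the nine-term variant is
  available via `TrendSpec(polynomial_terms=FULL_CUBIC_TERMS)`. Which
  mixed cubic terms a given study dropped is generally not recoverable, so
  neither variant is privileged beyond the default.
- Coordinates are centered (numerical conditioning and collinearity) and
  additionally divided by 1000 (km units). The scale is a package choice:
  meters cubed overflow the comfortable range of IRLS working weights. The
  centering constants and the fixed scale live on the fitted model, so
  scoring held-out locations is exact.
- Fitting is statsmodels GLM/Binomial. Separation is flagged when any
  |coefficient| exceeds 1e4 or the fit fails to converge; single-class
  items are errors. Probabilities are clamped to [1e-12, 1−1e-12] inside
  the deviance so residuals stay finite without materially moving
  estimates.

### Variography

- Matheron estimator, 40 equal-width bins to a maximum lag of half the
  maximum pairwise distance by default; both knobs are exposed because
  sensible values depend on the extent and the ranges in play. Empty bins
  are kept (N = 0, γ̂ = NaN) and excluded from fitting.
- Eight directional variograms at 0°, 22.5°, …, 157.5° with ±11.25°
  tolerance partition every pair exactly once.
- WLS objective: Σ N(h) (γ̂ − γ(θ; h))² / γ(θ; h)² (Cressie weights),
  minimized by bounded trust-region least squares from a
  method-of-moments start plus seeded random restarts (the surface is
  multimodal; 4–8 restarts suffice at these sizes). Candidates are all
  requested single families and ordered family pairs; Matérn smoothness is
  profiled over the grid {0.5, 1.0, 1.5, 2.5}. Ties break on weighted SSE
  then on fewer parameters. Range lower bound 1e-6 km (fits that want a
  vanishing range report this boundary value).
- Semivariogram families: spherical and cubic reach their sill exactly at
  the range parameter; exponential, Gaussian and Matérn use the distance
  parameter convention (sill approached asymptotically); sine-hole is
  γ(h) = c[1 − sin(πh/a)/(πh/a)]; power is γ(h) = b·h^p, p ∈ (0, 2].
- The anisotropy label is a quantitative surrogate for what is usually a
  visual judgement: "None" when all directional sills and practical ranges
  sit within 20% of the omnidirectional fit; "≥ Mid-range" when the
  directional curves track the omnidirectional curve within 20% up to the
  omnidirectional practical range but diverge beyond it; otherwise "Yes"
  with the most deviant axis. The 20% tolerance is a package definition,
  not an estimated quantity.

### Kriging

- Neighborhoods: all training points within 1.3 km, or the nearest 30 when
  the radius holds fewer — the local rule of the study design. Degenerate
  neighborhoods (a handful of points) are used with a warning rather than
  refused.
- The OK system is solved in semivariogram form with a Lagrange
  multiplier; weights sum to one by construction (checked to 1e-9 in the
  tests). The γ-form is used deliberately: power structures have no finite
  sill, so a covariance formulation would exclude them.
- Exactly co-located training points are averaged before solving
  (duplicates make the system singular). Systems with condition number
  above 1e12 fall back to a least-squares pseudo-solve.

### Back-transformation

The kriged quantity is a deviance residual; turning d* into a
probability-scale residual needs an inverse map. The binary deviance
formula extended literally to continuous pseudo-responses is discontinuous
at u = p̂ and non-monotone for p̂ ≠ ½, so the package inverts the
saturated-likelihood continuous deviance

d(u) = sign(u − p̂) · sqrt(2 [ u ln(u/p̂) + (1−u) ln((1−u)/(1−p̂)) ]),

which coincides with the binary residual at u ∈ {0, 1} (the saturated term
vanishes there), is zero at u = p̂, and is strictly monotone — so bisection
(64 iterations, ~1e-10) is well-posed. d* beyond the attainable interval
[d(0), d(1)] is clamped to the boundary, bounding |r*| by max(p̂, 1−p̂).
This inversion is an interpretation, not an established convention; an
identity mode (d* used directly as the raw residual) is provided for
sensitivity analysis and gives qualitatively similar rankings in our
synthetic runs.

## Probability surfaces

Nadaraya–Watson ratio of Gaussian-kernel-weighted Yes-mass to total mass on
a regular grid. Bandwidth is chosen by leave-one-out likelihood
cross-validation over 16 log-spaced candidates from the mean
nearest-neighbor distance to a quarter of the extent (ties to the smaller
candidate); probabilities are clipped to [1e-6, 1−1e-6] inside the CV
likelihood. Cells with total kernel weight below a floor revert to the
overall prevalence. Rendering uses a diverging palette with its white
midpoint at the prevalence.

## Block-group correlations

Full-model predictions (trend at the reference rater plus kriged residual)
at k = 10 uniform random points per areal unit are treated as 10
imputations. Pearson correlations are computed across units within each
imputation, Fisher-z transformed, pooled by Rubin's rules (mean of z;
total variance = within + (1 + 1/m)·between, within = 1/(n−3)), and
back-transformed. Pooling on the z scale is chosen because Rubin's rules
assume approximate normality, which r itself violates near ±1.

## The synthetic generator

The generator defines the study conditions under which everything is
tested; it is an assumption about a plausible data-generating process, not
a reconstruction of any real audit (whose true process is unknowable).

- **Locations.** Uniform candidates on a featureless plane, thinned to a
  hard minimum separation d, with d adjusted by bisection until the mean
  nearest-neighbor distance is within one empirical standard deviation of
  the 150 m target. At the study density (25.3 points/km²; ~8000 points
  over ~330 km²) this converges to a mean spacing of ≈154 m (sd ≈22 m).
  There is no road network: real audit points lie along streets, which
  concentrates them on one-dimensional structures; the plane sampler
  reproduces the spacing statistics but not that geometry.
- **Latent fields.** Zero-mean Gaussian random fields with covariance
  C(h) = sill − γ(h), drawn by dense Cholesky with 1e-8 diagonal jitter.
  Exactness was preferred over scalability; n is capped at 5000 points and
  the default test scale is 2000. Sine-hole (and power) structures are
  excluded from the generative side — hole-effect covariances are not
  positive definite in 2-D for all parameters — so the generator draws
  from spherical/exponential/Gaussian/Matérn/nugget only, while the
  fitting side still offers the full family set.
- **Responses.** P(Yes) = inverse-logit(trend + rater offset + field),
  recorded in the survey 1=Yes/2=No coding. Four raters by default with
  logit offsets (+0.6, 0, −0.6, 0) — systematic disagreement of the size
  that makes rater adjustment visibly worthwhile. When a prevalence target
  is given the intercept is calibrated by bisection against the realized
  field and offsets, so the marginal prevalence hits the target exactly in
  expectation rather than drifting with the field variance.
- **Block groups.** The extent is partitioned row-wise into exactly
  n_units rectangles (671 by default). Covariates are ρ·z + √(1−ρ²)·noise
  around the standardized unit-mean latent field, then shifted/scaled to
  census-plausible means; default ρ values encode the qualitative pattern
  of disorder correlating positively with mobility/density and negatively
  with home value and majority-white composition.

What passing tests on this generator show: the pipeline recovers known
trend and rater effects, fits variogram parameters consistently,
krige-predicts with the exactness and unbiasedness properties OK
guarantees, and converts small-scale structure into held-out AUC gains.
What they do not show: behavior under road-constrained geometry,
informative rater-to-location assignment, item-specific missingness, or
real census dependence structures.

## Problem sizes and test design

Desk-scale sizes are used throughout: n = 2000 locations for pipeline
properties (validation n = 200 under the 90-10 split), n ≈ 8000 for the
spacing check, 5 replicate fields for variogram recovery. Two choices are
worth flagging honestly:

- Single-realization WLS variogram estimates at n = 2000 have sampling
  noise well above 25% in the range parameter (the nugget–range trade-off
  is weakly identified when the extent is only a few multiples of the
  range). The recovery test therefore pools the five replicate estimates
  (median) before comparing to truth — the estimator is consistent, and
  pooling across replicates is how that is demonstrated at this scale.
- The "full model beats trend-only" direction property is checked across
  12 seeded replicates under strong small-scale structure (exponential
  sill 3, range 2 km, nugget 0.02 on the logit scale, zero true trend) and
  must hold in ≥95% of them. Under weaker structure the comparison is
  genuinely close to noise at validation n = 200, which mirrors the fact
  that the benefit of Kriging scales with the structured fraction of
  residual variance.

## Known limitations

- The back-transformation is an interpretation (see above); results on the
  probability scale inherit it, though AUC is insensitive to any monotone
  choice within a variant.
- Local OK ignores the uncertainty of the fitted variogram and of the
  trend; kriging variances are conditional on both.
- The anisotropy classifier reduces a judgement call to two tolerances; it
  agrees with the obvious cases (isotropic, 3:1 geometric anisotropy) but
  the boundary between "≥ Mid-range" and "Yes" is convention.
- `summarize_results_table` reports means computed from its input table;
  group means match a printed source only as closely as that source's own
  rounding allows.
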