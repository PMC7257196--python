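# auditkrige

Spatial prediction of binary neighborhood-audit responses by **regression
Kriging**: a logistic large-scale trend (optionally adjusted for rater) is
removed first, the deviance residuals are modeled geostatistically and
kriged locally, and the back-transformed residual is added to the scored
trend to give a held-out probability evaluated by RMSPE and ROC AUC.

The package is aimed at spatial epidemiologists and built-environment
researchers working with point-based ("drop-and-spin") virtual audits —
binary items such as *garbage present*, *sidewalk complete* or *pedestrian
signal* rated at thousands of locations across a county-scale region by a
handful of trained raters. Two questions drive the analysis: how far does
one audited point generalize (spatial autocorrelation and predictive
accuracy), and how much does systematic rater disagreement cost (rater
adjustment)?

## The model

For item response Y(s) ∈ {0, 1} at planar location s = (x, y):

```
logit P(Y=1 | s, rater) = β₀ + β₁x + β₂y + β₃x² + β₄y² + β₅xy + β₆x³ + β₇y³
                          + β₈R₁ + β₉R₂ + β₁₀R₃ + ε(s)
```

with coordinates centered to mean zero, raters 1–3 dummy-coded against
reference rater 4, and ε the deviance residual carrying the small-scale
spatial signal. The residual field is summarized by an empirical
semivariogram γ̂(h) and fit by weighted least squares (weights N(h)/γ(h)²)
with **nested** theoretical models — nugget plus up to two structures from
{spherical, exponential, Gaussian, Matérn, cubic, sine-hole, power} — so
autocorrelation at two scales can coexist. Held-out residuals are predicted
by **local ordinary Kriging** (search radius 1.3 km, or the nearest 30
training points if fewer fall inside), solved in the semivariogram form
with a Lagrange multiplier so that power models without a finite sill work
unchanged. The kriged deviance residual is inverted to a probability-scale
residual through the monotone continuous deviance map and added to the
scored trend, clipped to [0, 1].

Around the core pipeline the package provides kernel probability surfaces
(Gaussian kernel, leave-one-out likelihood CV bandwidth, divergent
rendering anchored at item prevalence), block-group-level pooled
correlations of predicted responses with census-style covariates (Rubin's
rules on the Fisher-z scale, 10 prediction points per unit treated as
imputations), and a synthetic-data generator that emulates the audit design
— ~150 m mean point spacing, latent Gaussian random fields with nested
covariance, four raters with systematic logit offsets, and census-like
areal units — so every stage is testable without restricted data.

## Worked example

```python
import auditkrige as ak

dataset, _ = ak.simulate_item_dataset(n_points=2000, seed=4, item_name="garbage")
result = ak.run_item(ak.RunConfig(seed=4), dataset, "garbage")
```

(`examples/04_kriging_cross_validation.py`) prints:

```
               detrending  rmspe  auc_large_scale  auc_full  pct_change_scale  pct_change_rater  nugget   accuracy
        3rd order spatial 0.4385           0.6515    0.7711           18.3680               NaN  1.0483 Acceptable
3rd order spatial + rater 0.4421           0.6310    0.7708           22.1698           -0.0399  1.0313 Acceptable
```

Reading the row: on the 10% held-out locations the cubic trend alone
discriminates at AUC 0.65; adding the kriged residual lifts it to 0.77
(+18–22%), the direction the method is designed to demonstrate. The fitted
nugget (~1.0 of a total sill ~1.1) says most residual variance is
unstructured at the shortest distances — typical of noisy binary ratings —
yet the structured fraction still buys real predictive accuracy.

The other scripts in `examples/` walk through each capability one at a
time: location sampling, trend fitting and rater contrasts, variography and
nested model ranking, probability surfaces, block-group pooled
correlations, and the packaged published-table summaries. A thin CLI
(`auditkrige simulate|run-item|run-all|surface|report`) wraps the same
functions.

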