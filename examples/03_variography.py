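"""Empirical semivariogram of deviance residuals and nested WLS fitting.

The binned estimator summarizes how residual dissimilarity grows with
distance; candidate single and nested (two-structure) theoretical models
are fit by weighted least squares and ranked by weighted SSE.
"""

import numpy as np

import auditkrige as ak

dataset, _ = ak.simulate_item_dataset(n_points=2000, seed=5,
                                      item_name="garbage")
model = ak.fit_trend(dataset, "garbage", ak.TrendSpec(include_rater=True))
resid = ak.deviance_residuals(model, dataset)

emp = ak.empirical_semivariogram(resid[["x_m", "y_m"]].to_numpy(),
                                 resid["residual"].to_numpy(),
                                 n_bins=30, max_lag_km=5.0)
lag, gam, n = emp.nonempty()
print("first bins (lag km, gamma-hat, pairs):")
for k in range(4):
    print(f"  {lag[k]:.2f}  {gam[k]:.3f}  {n[k]}")

best, ledger = ak.fit_nested_wls(
    emp,
    candidates=[("spherical",), ("exponential",), ("gaussian",),
                ("exponential", "spherical"), ("spherical", "sine_hole")],
    n_starts=6, seed=11, return_ledger=True)

print("\nbest model:", " + ".join(best.families) or "nugget only")
print("  nugget", round(best.nugget, 3))
for s in best.structures:
    print(f"  {s.family}: partial sill {s.partial_sill:.3f}, "
          f"range {s.range_km:.3f} km")
print("  total sill", None if best.total_sill is None
      else round(best.total_sill, 3))
print("  weighted SSE", round(best.weighted_sse, 2))
print("\ncandidate ranking (weighted SSE):")
for m in ledger[:4]:
    print(f"  {'-'.join(m.families):30s} {m.weighted_sse:10.2f}")
# A rising gamma-hat that flattens toward a sill is the signature of
# small-scale autocorrelation; the sill decomposes into nugget plus the
# partial sills of the fitted structures.
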