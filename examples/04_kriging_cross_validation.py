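"""Full per-item analysis: detrend, krige held-out residuals, evaluate.

Reproduces the per-item report shape of the study — RMSPE, ROC AUC of the
large-scale-only and full (trend + Kriging) models, percent changes from
rater adjustment, and the accuracy label.
"""

import pandas as pd

import auditkrige as ak

dataset, _ = ak.simulate_item_dataset(n_points=2000, seed=4,
                                      item_name="garbage")
result = ak.run_item(ak.RunConfig(seed=4), dataset, "garbage")

table = pd.DataFrame([r.as_dict() for r in result["rows"]])
cols = ["detrending", "rmspe", "auc_large_scale", "auc_full",
        "pct_change_scale", "pct_change_rater", "nugget", "accuracy"]
print(table[cols].round(4).to_string(index=False))
# auc_full > auc_large_scale on both rows: modeling the small-scale
# residual structure by local ordinary Kriging adds real held-out
# discrimination beyond the cubic trend, mirroring the study's direction.
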