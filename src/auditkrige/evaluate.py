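"""Back-transformation of kriged deviance residuals, assembled predictions
and the cross-validation evaluation surface (RMSPE, ROC AUC, percent
changes, accuracy labels, summary counts).

The kriged quantity is a deviance residual; turning it back into a raw
(probability-scale) residual requires inverting the deviance map. We use
the saturated-likelihood continuous deviance

    d(u) = sign(u - p) * sqrt(2 [u ln(u/p) + (1-u) ln((1-u)/(1-p))]),

which coincides with the binary deviance residual at u in {0, 1}, is zero
at u = p, and is continuous and strictly monotone in u on [0, 1] — so the
inversion is a well-posed root find. Kriged values beyond the attainable
interval [d(0), d(1)] are clamped to the boundary. An identity mode
(kriged value used directly as the raw residual) is provided for
sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

_P_EPS = 1e-12
_BISECT_TOL = 1e-10

DISORDER = "neighborhood physical disorder"


class EvaluationError(ValueError):
    pass


def _cont_deviance(u, p):
    """Signed continuous deviance of pseudo-response u against p."""
    u = np.asarray(u, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(u > 0, u * np.log(u / p), 0.0)
        t2 = np.where(u < 1, (1 - u) * np.log((1 - u) / (1 - p)), 0.0)
    mag = np.sqrt(np.maximum(2.0 * (t1 + t2), 0.0))
    return np.sign(u - p) * mag


def invert_deviance(d, p, mode: str = "deviance"):
    """Raw residual r* = u - p implied by a kriged deviance residual d.

    Solves d(u) = d for the pseudo-response u in [0, 1] by bisection on the
    monotone continuous deviance, after clamping d to the attainable
    interval [d(0), d(1)]. Exact for binary observations:
    invert(deviance(y, p), p) = y - p.
    """
    d = np.asarray(d, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise EvaluationError("trend probabilities must lie strictly in (0, 1)")
    scalar = d.ndim == 0 and p_arr.ndim == 0
    d, p_arr = np.atleast_1d(d), np.atleast_1d(p_arr)
    d, p_arr = np.broadcast_arrays(d, p_arr)

    if mode == "identity":
        r = np.clip(d, -p_arr, 1 - p_arr)
        return r[0] if scalar else r
    if mode != "deviance":
        raise EvaluationError(f"unknown back-transform mode {mode!r}")

    d_lo = _cont_deviance(np.zeros_like(p_arr), p_arr)
    d_hi = _cont_deviance(np.ones_like(p_arr), p_arr)
    d = np.clip(d, d_lo, d_hi)

    lo = np.zeros_like(p_arr)
    hi = np.ones_like(p_arr)
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        too_low = _cont_deviance(mid, p_arr) < d
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
        if np.max(hi - lo) < _BISECT_TOL:
            break
    u = 0.5 * (lo + hi)
    # snap the exact fixed point and boundaries
    u = np.where(np.abs(d) < _BISECT_TOL, p_arr, u)
    u = np.where(d >= d_hi - _BISECT_TOL, 1.0, u)
    u = np.where(d <= d_lo + _BISECT_TOL, 0.0, u)
    r = u - p_arr
    return r[0] if scalar else r


def assemble_predictions(
    trend_scores: pd.DataFrame,
    kriged: pd.DataFrame,
    observations: pd.DataFrame,
    mode: str = "deviance",
) -> pd.DataFrame:
    """Merge trend probabilities, kriged residuals and observed responses.

    Inputs are id-keyed frames: trend_scores(id, p_trend),
    kriged(id, predicted_residual), observations(id, y). The assembled
    prediction is clip(p_trend + r*, 0, 1).
    """
    ids = [set(f["id"]) for f in (trend_scores, kriged, observations)]
    union = set.union(*ids)
    inter = set.intersection(*ids)
    if union != inter:
        raise EvaluationError(f"id mismatch; orphans: {sorted(union - inter)[:10]}")
    merged = (trend_scores.merge(kriged[["id", "predicted_residual"]], on="id")
              .merge(observations[["id", "y"]], on="id"))
    p = np.clip(merged["p_trend"].to_numpy(dtype=float), _P_EPS, 1 - _P_EPS)
    d = merged["predicted_residual"].to_numpy(dtype=float)
    r = invert_deviance(d, p, mode=mode)
    merged["raw_residual"] = r
    merged["y_hat"] = np.clip(p + r, 0.0, 1.0)
    return merged


def rmspe(y, y_hat) -> float:
    """Root mean squared prediction error of probabilities against 0/1."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0:
        raise EvaluationError("empty record set")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def roc_auc(y, scores) -> float:
    """Concordance probability (ties count 1/2); NaN if one class only."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        warnings.warn("single-class validation set; AUC undefined")
        return float("nan")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def percent_change(before: float, after: float) -> float:
    if before == 0:
        raise EvaluationError("percent change undefined for zero baseline")
    return 100.0 * (after - before) / before


def accuracy_label(auc: float) -> str:
    """Conventional discrimination taxonomy on half-open intervals."""
    if not 0 <= auc <= 1:
        raise EvaluationError("AUC must be in [0, 1]")
    if auc == 0.5:
        return "None"
    if auc >= 0.9:
        return "Outstanding"
    if auc >= 0.8:
        return "Excellent"
    if auc >= 0.7:
        return "Acceptable"
    return "less than Acceptable"


RATER_VARIANT = "3rd order spatial + rater"
SPATIAL_VARIANT = "3rd order spatial"


def summarize_results_table(
    table: pd.DataFrame,
    outlier_items: tuple[str, ...] = (),
) -> dict:
    """Headline counts and group means from a full 31x2 evaluation table.

    Expects one row per item x detrending variant with columns item, group,
    detrending, auc_large_scale, auc_full, pct_change_rater, rmspe,
    pct_rmspe_change, nugget. ``outlier_items`` are excluded from the
    overall mean rater change only (group means keep all items).
    """
    required = {"item", "group", "detrending", "auc_large_scale", "auc_full"}
    missing = required - set(table.columns)
    if missing:
        raise EvaluationError(f"missing columns: {sorted(missing)}")
    items = table["item"].unique()
    counts = table.groupby("item")["detrending"].nunique()
    incomplete = counts[counts < 2].index.tolist()
    if incomplete:
        raise EvaluationError(f"items missing a detrending variant: {incomplete}")

    full_auc = table["auc_full"].to_numpy(dtype=float)
    summary = {
        "n_items": int(len(items)),
        "n_full_models": int(len(table)),
        "full_models_outstanding": int(np.sum(full_auc >= 0.9)),
        "full_models_below_acceptable": int(np.sum(full_auc < 0.7)),
        "full_beats_large_scale": int(
            np.sum(full_auc > table["auc_large_scale"].to_numpy(dtype=float))
        ),
    }

    rater = table[table["detrending"] == RATER_VARIANT].set_index("item")
    spatial = table[table["detrending"] == SPATIAL_VARIANT].set_index("item")

    if "pct_change_rater" in table.columns:
        chg = rater["pct_change_rater"].astype(float)
        summary["items_improved_by_rater"] = int((chg > 0).sum())
        keep = chg[~chg.index.isin(outlier_items)]
        summary["mean_rater_pct_change"] = float(keep.mean())
        group_means = {}
        for group, sub in rater.groupby("group"):
            group_means[group] = float(sub["pct_change_rater"].astype(float).mean())
        summary["group_mean_rater_pct_change"] = group_means
    if "pct_rmspe_change" in table.columns:
        summary["items_rmspe_lower_with_rater"] = int(
            (rater["pct_rmspe_change"].astype(float) < 0).sum()
        )
    if "nugget" in table.columns:
        nr = rater["nugget"].astype(float)
        ns = spatial["nugget"].astype(float).reindex(nr.index)
        summary["items_nugget_lower_with_rater"] = int((nr < ns).sum())
    return summary


@dataclass
class EvaluationRow:
    """One line of the per-item evaluation report."""

    item: str
    detrending: str
    rmspe: float
    auc_large_scale: float
    auc_full: float
    pct_change_scale: float
    pct_change_rater: float | None = None
    pct_rmspe_change: float | None = None
    nugget: float | None = None
    accuracy: str | None = None
    group: str | None = None

    def as_dict(self) -> dict:
        return dict(vars(self))
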