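"""Per-item orchestration of the full analysis: train/validation split,
logistic detrending (with and without rater), deviance-residual
variography, nested WLS model selection, local ordinary Kriging of the
validation residuals, back-transformation, assembled predictions, and the
RMSPE / ROC-AUC evaluation surface.

All randomness flows from a single master seed through named per-stage
streams, and the 90-10 split is shared between the rater and no-rater
variants of an item so their comparison is paired.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate, variogram
from .audit_io import AuditDataset, evaluation_table_from_fixtures
from .evaluate import EvaluationRow
from .kriging import KrigingPlan, krige_field
from .trend import TrendSpec, deviance_residuals, fit_trend
from .variogram import (
    classify_anisotropy,
    directional_semivariograms,
    empirical_semivariogram,
    fit_nested_wls,
)

logger = logging.getLogger("auditkrige")

SPATIAL = evaluate.SPATIAL_VARIANT
RATER = evaluate.RATER_VARIANT

#: candidate family tuples used by default at pipeline scale — a compact
#: subset of the full single+nested grid, enough to cover one- and
#: two-scale structure without an exhaustive family search per item
DEFAULT_CANDIDATES: tuple[tuple[str, ...], ...] = (
    ("spherical",), ("exponential",), ("gaussian",),
    ("exponential", "spherical"), ("spherical", "sine_hole"),
    ("matern", "sine_hole"),
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Knobs for a full run; defaults mirror the study conditions."""

    split_fraction: float = 0.9
    seed: int = 0
    plan: KrigingPlan = field(default_factory=KrigingPlan)
    n_bins: int = 40
    max_lag_km: float | None = None
    candidates: tuple[tuple[str, ...], ...] = DEFAULT_CANDIDATES
    matern_smoothness_grid: tuple[float, ...] = (0.5, 1.5)
    n_starts: int = 4
    backtransform: str = "deviance"
    run_directional: bool = False
    directional_bins: int = 20

    def stage_seed(self, stage: str, item: str = "") -> int:
        # stable across processes (unlike hash())
        key = f"{self.seed}:{stage}:{item}".encode()
        return zlib.crc32(key) % (2**31 - 1)


def split_train_validation(df: pd.DataFrame, fraction: float, seed: int):
    """Uniform random 90-10 split (no stratification)."""
    if not 0 < fraction < 1:
        raise PipelineError("split fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(df)
    n_train = int(round(fraction * n))
    perm = rng.permutation(n)
    return (df.iloc[perm[:n_train]].reset_index(drop=True),
            df.iloc[perm[n_train:]].reset_index(drop=True))


def _run_variant(train, valid, item, include_rater, config, group=None):
    """Fit one detrending variant end to end; returns row + artifacts."""
    detrending = RATER if include_rater else SPATIAL
    spec = TrendSpec(include_rater=include_rater)
    model = fit_trend(train, item, spec)
    resid = deviance_residuals(model, train)

    emp = empirical_semivariogram(
        resid[["x_m", "y_m"]].to_numpy(), resid["residual"].to_numpy(),
        n_bins=config.n_bins, max_lag_km=config.max_lag_km,
    )
    vgm_seed = config.stage_seed("wls", item)
    vgm = fit_nested_wls(emp, candidates=list(config.candidates),
                         matern_smoothness_grid=config.matern_smoothness_grid,
                         n_starts=config.n_starts, seed=vgm_seed)
    vgm.item, vgm.detrending = item, detrending

    anisotropy = None
    if config.run_directional:
        dirs = directional_semivariograms(
            resid[["x_m", "y_m"]].to_numpy(), resid["residual"].to_numpy(),
            n_bins=config.directional_bins, max_lag_km=config.max_lag_km,
        )
        dir_models = {}
        for angle, demp in dirs.items():
            try:
                dir_models[angle] = fit_nested_wls(
                    demp, candidates=list(config.candidates),
                    matern_smoothness_grid=config.matern_smoothness_grid,
                    n_starts=config.n_starts, seed=vgm_seed)
            except variogram.VariogramError:
                logger.warning("direction %s° excluded (too few pairs)", angle)
        anisotropy = classify_anisotropy(dir_models, vgm)

    kriged = krige_field(valid, resid, vgm, config.plan)

    p_trend = model.predict(valid)
    scores = pd.DataFrame({"id": valid["id"], "p_trend": p_trend})
    obs = valid[["id", "y"]]
    records = evaluate.assemble_predictions(scores, kriged, obs,
                                            mode=config.backtransform)
    auc_large = evaluate.roc_auc(obs["y"], p_trend)
    auc_full = evaluate.roc_auc(records["y"], records["y_hat"])
    row = EvaluationRow(
        item=item,
        detrending=detrending,
        rmspe=evaluate.rmspe(records["y"], records["y_hat"]),
        auc_large_scale=auc_large,
        auc_full=auc_full,
        pct_change_scale=evaluate.percent_change(auc_large, auc_full),
        nugget=vgm.nugget,
        accuracy=evaluate.accuracy_label(auc_full),
        group=group,
    )
    artifacts = {"trend": model, "residuals": resid, "empirical": emp,
                 "variogram": vgm, "kriged": kriged, "records": records,
                 "anisotropy": anisotropy}
    return row, artifacts


def run_item(config: RunConfig, dataset: AuditDataset, item: str,
             group: str | None = None) -> dict:
    """Both detrending variants for one item on a shared split.

    Returns {"rows": [EvaluationRow, EvaluationRow], "artifacts": {...}}.
    """
    df = dataset.analysis_frame(item)
    if df["y"].nunique() < 2:
        raise PipelineError(f"item {item!r} has one response class")
    train, valid = split_train_validation(
        df, config.split_fraction, config.stage_seed("split", item))

    rows, artifacts = [], {}
    for include_rater in (False, True):
        row, art = _run_variant(train, valid, item, include_rater, config, group)
        rows.append(row)
        artifacts[row.detrending] = art

    sp, ra = rows
    ra.pct_change_rater = evaluate.percent_change(sp.auc_full, ra.auc_full)
    ra.pct_rmspe_change = evaluate.percent_change(sp.rmspe, ra.rmspe)
    return {"rows": rows, "artifacts": artifacts, "train": train, "valid": valid}


def run_all(config: RunConfig, dataset: AuditDataset,
            groups: dict[str, str] | None = None) -> dict:
    """Every item in the dataset; failures are recorded, the run continues."""
    rows, failures = [], {}
    for item in dataset.items:
        try:
            result = run_item(config, dataset, item,
                              group=(groups or {}).get(item))
            rows.extend(result["rows"])
        except Exception as exc:  # keep going, report at the end
            logger.exception("item %r failed", item)
            failures[item] = str(exc)
    table = pd.DataFrame([r.as_dict() for r in rows])
    summary = None
    if not table.empty and not failures:
        try:
            summary = evaluate.summarize_results_table(table)
        except evaluate.EvaluationError:
            pass
    return {"table": table, "summary": summary, "failures": failures}


def predict_at_locations(artifact: dict, locations: pd.DataFrame,
                         plan: KrigingPlan | None = None,
                         mode: str = "deviance") -> pd.DataFrame:
    """Full-model P(Yes) at arbitrary unaudited locations.

    ``artifact`` is one variant's entry from run_item (trend model, training
    residuals and fitted variogram). Rater is scored at the reference level
    since unaudited locations have none. ``locations`` needs id, x_m, y_m.
    """
    from .evaluate import invert_deviance

    model = artifact["trend"]
    resid = artifact["residuals"]
    vgm = artifact["variogram"]
    p = model.predict(locations, fallback_reference=True)
    kriged = krige_field(locations[["id", "x_m", "y_m"]], resid, vgm,
                         plan or KrigingPlan())
    p_clip = np.clip(p, 1e-12, 1 - 1e-12)
    r = invert_deviance(kriged["predicted_residual"].to_numpy(), p_clip,
                        mode=mode)
    out = locations[["id", "x_m", "y_m"]].copy()
    out["p_trend"] = p
    out["y_hat"] = np.clip(p + r, 0.0, 1.0)
    return out


def report_from_fixtures(outlier_items: tuple[str, ...] = ()) -> dict:
    """Summary counts recomputed from the packaged published tables."""
    table = evaluation_table_from_fixtures()
    return evaluate.summarize_results_table(table, outlier_items=outlier_items)


def write_report(result: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["table"].to_csv(out / "evaluation.csv", index=False)
    if result.get("summary") is not None:
        (out / "summary.json").write_text(json.dumps(result["summary"], indent=2))
    if result.get("failures"):
        (out / "failures.json").write_text(json.dumps(result["failures"], indent=2))
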