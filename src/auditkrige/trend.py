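"""Large-scale detrending of binary audit responses.

Each item is regressed (maximum-likelihood logistic fit) on a centered
cubic polynomial in the planar coordinates, optionally with rater dummy
codes, and the deviance residuals carry the small-scale spatial signal on
to the variography stage.

Coordinates are centered to mean zero (and scaled to kilometers) before the
polynomial expansion, which keeps the design well conditioned; the centering
constants are stored on the fitted model so held-out locations are scored
in the same frame.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: seven-term spatial polynomial: {x, y, x2, y2, xy, x3, y3}
DEFAULT_TERMS: tuple[tuple[int, int], ...] = (
    (1, 0), (0, 1), (2, 0), (0, 2), (1, 1), (3, 0), (0, 3),
)

#: full 9-term cubic (adds the mixed cubics x2y and xy2)
FULL_CUBIC_TERMS: tuple[tuple[int, int], ...] = DEFAULT_TERMS + ((2, 1), (1, 2))

#: meters per design-matrix coordinate unit
COORD_SCALE_M = 1000.0

_CLAMP = 1e-12


class TrendError(ValueError):
    pass


def term_name(px: int, py: int) -> str:
    parts = []
    if px:
        parts.append("x" if px == 1 else f"x{px}")
    if py:
        parts.append("y" if py == 1 else f"y{py}")
    return "*".join(parts) or "1"


@dataclass(frozen=True)
class TrendSpec:
    """Which polynomial terms and whether rater dummies enter the model."""

    polynomial_terms: tuple[tuple[int, int], ...] = DEFAULT_TERMS
    include_rater: bool = False
    rater_reference: object | None = None  # default: last level in sorted order

    def __post_init__(self) -> None:
        if not self.polynomial_terms:
            raise TrendError("term list must be non-empty")
        for px, py in self.polynomial_terms:
            if px + py > 3:
                raise TrendError(f"total polynomial degree > 3 in term ({px},{py})")


def build_design(
    df: pd.DataFrame,
    spec: TrendSpec,
    centering: tuple[float, float] | None = None,
    rater_levels: list | None = None,
) -> tuple[pd.DataFrame, tuple[float, float], list]:
    """Design matrix (with intercept) for the trend regression.

    Returns (X, centering, rater_levels). ``centering`` holds the mean x/y
    in meters; pass the training values when scoring new locations.
    """
    if centering is None:
        # fitting path; scoring reuses stored centering and may hold 1 point
        if df[["x_m", "y_m"]].drop_duplicates().shape[0] < 2:
            raise TrendError("need at least two distinct locations")
        centering = (float(df["x_m"].mean()), float(df["y_m"].mean()))
    xc = (df["x_m"].to_numpy(dtype=float) - centering[0]) / COORD_SCALE_M
    yc = (df["y_m"].to_numpy(dtype=float) - centering[1]) / COORD_SCALE_M
    cols = {"const": np.ones(len(df))}
    for px, py in spec.polynomial_terms:
        cols[term_name(px, py)] = xc**px * yc**py
    X = pd.DataFrame(cols, index=df.index)

    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        warnings.warn("constant coordinate column; design is rank deficient")

    if spec.include_rater:
        if "rater" not in df.columns:
            raise TrendError("rater column required when include_rater=True")
        if rater_levels is None:
            levels = sorted(df["rater"].unique().tolist())
            ref = spec.rater_reference if spec.rater_reference is not None else levels[-1]
            if ref not in levels:
                raise TrendError(f"rater reference {ref!r} not among levels {levels}")
            rater_levels = [l for l in levels if l != ref] + [ref]
        non_ref = rater_levels[:-1]
        unseen = set(df["rater"].unique()) - set(rater_levels)
        if unseen:
            raise TrendError(f"unseen rater levels {sorted(unseen)}")
        for level in non_ref:
            X[f"rater_{level}"] = (df["rater"] == level).astype(float)
    else:
        rater_levels = []
    return X, centering, rater_levels


@dataclass
class TrendModel:
    """Fitted logistic spatial-trend model for one audit item."""

    item: str
    spec: TrendSpec
    params: pd.Series
    centering: tuple[float, float]
    rater_levels: list
    deviance: float
    converged: bool
    bse: pd.Series | None = None  # asymptotic standard errors

    def design(self, df: pd.DataFrame) -> pd.DataFrame:
        X, _, _ = build_design(df, self.spec, self.centering,
                               self.rater_levels or None)
        return X[self.params.index]

    def predict(self, df: pd.DataFrame, fallback_reference: bool = False) -> np.ndarray:
        """Scored P(Yes) at the rows of ``df`` (needs x_m, y_m [, rater])."""
        df = df.copy()
        if self.spec.include_rater:
            if "rater" not in df.columns:
                if not fallback_reference:
                    raise TrendError("rater column required for scoring")
                df["rater"] = self.rater_levels[-1]
            unseen = set(df["rater"].unique()) - set(self.rater_levels)
            if unseen:
                if not fallback_reference:
                    raise TrendError(f"unseen rater levels {sorted(unseen)}")
                df.loc[df["rater"].isin(unseen), "rater"] = self.rater_levels[-1]
        X = self.design(df)
        eta = X.to_numpy(dtype=float) @ self.params.to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "item": self.item,
            "polynomial_terms": list(map(list, self.spec.polynomial_terms)),
            "include_rater": self.spec.include_rater,
            "params": {k: float(v) for k, v in self.params.items()},
            "centering": list(self.centering),
            "rater_levels": self.rater_levels,
            "deviance": self.deviance,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "TrendModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        spec = TrendSpec(tuple(map(tuple, d["polynomial_terms"])), d["include_rater"])
        return cls(d["item"], spec, pd.Series(d["params"]), tuple(d["centering"]),
                   d["rater_levels"], d["deviance"], d["converged"])


def fit_trend(dataset, item: str, spec: TrendSpec = TrendSpec()) -> TrendModel:
    """Maximum-likelihood logistic fit of one item on the trend design.

    ``dataset`` is an AuditDataset or an analysis frame with columns
    id/x_m/y_m/rater/y (y in {0,1}).
    """
    df = dataset.analysis_frame(item) if hasattr(dataset, "analysis_frame") else dataset
    y = df["y"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise TrendError(f"item {item!r} has a single response class")
    X, centering, rater_levels = build_design(df, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
    params = pd.Series(res.params, index=X.columns)
    converged = bool(getattr(res, "converged", True))
    if not np.isfinite(params.to_numpy()).all() or np.abs(params).max() > 1e4:
        raise TrendError(
            f"logistic fit for {item!r} did not converge (possible separation); "
            f"max |coef| = {np.abs(params).max():.3g}"
        )
    return TrendModel(item, spec, params, centering, rater_levels,
                      float(res.deviance), converged,
                      bse=pd.Series(res.bse, index=X.columns))


def deviance_residual(y, p) -> np.ndarray:
    """Signed square-root deviance contribution of binary observations."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("fitted probabilities at {0,1} clamped for deviance")
    p = np.clip(p, _CLAMP, 1 - _CLAMP)
    dev2 = -2.0 * (y * np.log(p) + (1 - y) * np.log1p(-p))
    return np.sign(y - p) * np.sqrt(np.maximum(dev2, 0.0))


def deviance_residuals(model: TrendModel, dataset) -> pd.DataFrame:
    """Per-location deviance residuals of a fitted trend model.

    Returns a frame with columns id, x_m, y_m, residual.
    """
    df = (dataset.analysis_frame(model.item)
          if hasattr(dataset, "analysis_frame") else dataset)
    p = model.predict(df)
    eps = deviance_residual(df["y"].to_numpy(dtype=float), p)
    return pd.DataFrame({
        "id": df["id"].to_numpy(),
        "x_m": df["x_m"].to_numpy(dtype=float),
        "y_m": df["y_m"].to_numpy(dtype=float),
        "residual": eps,
    })


def score_trend(model: TrendModel, locations: pd.DataFrame,
                rater=None, fallback_reference: bool = False) -> np.ndarray:
    """Trend-component probabilities at arbitrary locations."""
    df = locations.copy()
    if rater is not None:
        df["rater"] = rater
    return model.predict(df, fallback_reference=fallback_reference)
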