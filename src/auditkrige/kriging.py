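"""Local ordinary Kriging of deviance residuals.

The ordinary-Kriging system is solved in its semivariogram form (with a
Lagrange multiplier enforcing unit weight sum), which remains valid for
power structures that have no finite sill, so no variogram-to-covariance
conversion is ever needed. Neighborhoods follow the study rule: all
training points within the search radius, or the nearest ``min_neighbors``
points when the radius holds fewer than that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .variogram import NestedVariogramModel

_COND_LIMIT = 1e12


class KrigingError(ValueError):
    pass


@dataclass(frozen=True)
class KrigingPlan:
    """Neighborhood rules for local ordinary Kriging.

    ``radius_km`` defaults to 1.3 km; when fewer than ``min_neighbors``
    training points fall inside, the radius grows to the nearest
    ``min_neighbors`` points.
    """

    radius_km: float = 1.3
    min_neighbors: int = 30
    max_neighbors: int | None = None

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise KrigingError("radius must be > 0")
        if self.min_neighbors < 1:
            raise KrigingError("min_neighbors must be >= 1")


@dataclass
class KrigedValue:
    id: object
    predicted_residual: float
    kriging_variance: float
    n_neighbors: int
    radius_used_km: float


def select_neighbors(
    target_xy_m: np.ndarray,
    train_xy_m: np.ndarray,
    plan: KrigingPlan,
    tree: cKDTree | None = None,
) -> tuple[np.ndarray, float]:
    """Indices of the training points used for one prediction.

    Returns (indices, radius actually used in km). If the whole training
    set is smaller than ``min_neighbors`` every point is returned.
    """
    if len(train_xy_m) == 0:
        raise KrigingError("no training points")
    if tree is None:
        tree = cKDTree(train_xy_m)
    target = np.asarray(target_xy_m, dtype=float)
    radius_m = plan.radius_km * 1000.0
    idx = tree.query_ball_point(target, radius_m)
    idx = np.asarray(idx, dtype=int)
    n_avail = len(train_xy_m)
    if len(idx) < min(plan.min_neighbors, n_avail):
        k = min(plan.min_neighbors, n_avail)
        dist, idx = tree.query(target, k=k)
        idx = np.atleast_1d(idx)
        radius_used = float(np.max(np.atleast_1d(dist))) / 1000.0
    else:
        radius_used = plan.radius_km
    if plan.max_neighbors is not None and len(idx) > plan.max_neighbors:
        d = np.linalg.norm(train_xy_m[idx] - target, axis=1)
        idx = idx[np.argsort(d)[: plan.max_neighbors]]
        radius_used = float(np.linalg.norm(train_xy_m[idx] - target, axis=1).max()) / 1000.0
    return idx, radius_used


def _dedupe(coords_m: np.ndarray, values: np.ndarray):
    """Average residuals at exactly co-located coordinates."""
    uniq, inverse = np.unique(coords_m, axis=0, return_inverse=True)
    if len(uniq) == len(coords_m):
        return coords_m, values
    sums = np.bincount(inverse, weights=values)
    counts = np.bincount(inverse)
    return uniq, sums / counts


def _solve_ok(coords_m: np.ndarray, values: np.ndarray, target_xy_m: np.ndarray,
              model: NestedVariogramModel):
    n = len(coords_m)
    d_km = np.linalg.norm(coords_m[:, None, :] - coords_m[None, :, :], axis=-1) / 1000.0
    gamma = model.semivariance(d_km)
    np.fill_diagonal(gamma, 0.0)
    d0_km = np.linalg.norm(coords_m - np.asarray(target_xy_m, dtype=float), axis=1) / 1000.0
    gamma0 = model.semivariance(d0_km)

    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = gamma
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    b = np.concatenate([gamma0, [1.0]])
    try:
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > _COND_LIMIT:
            raise np.linalg.LinAlgError("ill-conditioned OK system")
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    w, mu = sol[:n], sol[n]
    pred = float(w @ values)
    var = float(w @ gamma0 + mu)
    return pred, max(var, 0.0), w


def krige_point(
    target_xy_m: np.ndarray,
    neighbor_xy_m: np.ndarray,
    neighbor_values: np.ndarray,
    model: NestedVariogramModel,
    target_id=None,
    radius_used_km: float = np.nan,
) -> KrigedValue:
    """Ordinary-Kriging prediction at one location from its neighbors."""
    coords = np.asarray(neighbor_xy_m, dtype=float)
    values = np.asarray(neighbor_values, dtype=float)
    if len(coords) < 2:
        raise KrigingError("need at least two neighbors")
    coords, values = _dedupe(coords, values)
    pred, var, w = _solve_ok(coords, values, target_xy_m, model)
    return KrigedValue(target_id, pred, var, len(coords), radius_used_km)


def krige_field(
    validation: pd.DataFrame,
    training: pd.DataFrame,
    model: NestedVariogramModel,
    plan: KrigingPlan = KrigingPlan(),
) -> pd.DataFrame:
    """Local OK at every validation location.

    ``training`` needs columns id, x_m, y_m, residual; ``validation`` needs
    id, x_m, y_m. Returns one row per validation location with the kriged
    residual, kriging variance, neighbor count and radius used.
    """
    overlap = set(validation["id"]) & set(training["id"])
    if overlap:
        raise KrigingError(f"train/validation ids overlap: {sorted(overlap)[:5]}")
    train_xy = training[["x_m", "y_m"]].to_numpy(dtype=float)
    train_val = training["residual"].to_numpy(dtype=float)
    tree = cKDTree(train_xy)
    rows = []
    for _, rec in validation.iterrows():
        target = np.array([rec["x_m"], rec["y_m"]], dtype=float)
        idx, radius = select_neighbors(target, train_xy, plan, tree=tree)
        if len(idx) < 2:
            warnings.warn(f"degenerate neighborhood at id {rec['id']!r}")
            pred = float(train_val[idx].mean()) if len(idx) else 0.0
            rows.append(KrigedValue(rec["id"], pred, np.nan, len(idx), radius))
            continue
        try:
            kv = krige_point(target, train_xy[idx], train_val[idx], model,
                             target_id=rec["id"], radius_used_km=radius)
        except KrigingError as exc:
            raise KrigingError(f"kriging failed at id {rec['id']!r}: {exc}") from exc
        rows.append(kv)
    return pd.DataFrame([vars(kv) for kv in rows])
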