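"""Empirical and theoretical semivariograms of deviance residuals.

The semivariogram gamma(h) is half the expected squared difference between
field values a distance h apart. Small-scale structure left after logistic
detrending is summarized by an empirical (binned) semivariogram and modeled
by a nugget plus one or two theoretical structures ("nested" models), fit by
weighted least squares with Cressie weights N(h) / gamma(theta; h)^2.

Distances are kilometers throughout this module; audit coordinates are
meters and are converted at entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist
from scipy.special import gamma as gamma_fn, kv

FAMILIES = (
    "nugget", "spherical", "exponential", "gaussian", "matern",
    "cubic", "sine_hole", "power",
)

#: families whose semivariance is non-decreasing in distance
MONOTONE_FAMILIES = ("spherical", "exponential", "gaussian", "cubic", "power")

#: families with a valid 2-D covariance, usable for field simulation
SIMULATABLE_FAMILIES = ("nugget", "spherical", "exponential", "gaussian", "matern")

MATERN_SMOOTHNESS_GRID = (0.5, 1.0, 1.5, 2.5)

RANGE_LOWER_BOUND_KM = 1e-6


class VariogramError(ValueError):
    pass


@dataclass(frozen=True)
class VariogramStructure:
    """One theoretical structure: family plus (partial sill, range).

    For the power family ``partial_sill`` is the coefficient b and
    ``range_km`` the exponent p in gamma(h) = b * h**p (no finite sill).
    ``smoothness`` is the Matérn shape parameter and is ignored otherwise.
    """

    family: str
    partial_sill: float
    range_km: float
    smoothness: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise VariogramError(f"unknown family {self.family!r}")
        if self.family != "nugget":
            if self.partial_sill < 0:
                raise VariogramError("partial sill must be >= 0")
            if self.family == "power":
                if not 0 < self.range_km <= 2:
                    raise VariogramError("power exponent p must be in (0, 2]")
            elif self.range_km <= 0:
                raise VariogramError("range must be > 0")
        if self.family == "matern" and self.smoothness is None:
            object.__setattr__(self, "smoothness", 0.5)

    def semivariance(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if np.any(h < 0):
            raise VariogramError("negative lag distance")
        c, a = self.partial_sill, self.range_km
        if self.family == "nugget":
            return np.where(h > 0, c, 0.0)
        if self.family == "spherical":
            r = np.minimum(h / a, 1.0)
            return c * (1.5 * r - 0.5 * r**3)
        if self.family == "exponential":
            return c * (1.0 - np.exp(-h / a))
        if self.family == "gaussian":
            return c * (1.0 - np.exp(-((h / a) ** 2)))
        if self.family == "matern":
            nu = float(self.smoothness)
            r = h / a
            out = np.full_like(r, c, dtype=float)
            small = r > 0
            x = r[small]
            with np.errstate(over="ignore", invalid="ignore"):
                corr = (2.0 ** (1 - nu) / gamma_fn(nu)) * (x**nu) * kv(nu, x)
            corr = np.nan_to_num(corr, nan=0.0, posinf=1.0)
            out[small] = c * (1.0 - np.clip(corr, 0.0, 1.0))
            out[~small] = 0.0
            return out
        if self.family == "cubic":
            r = np.minimum(h / a, 1.0)
            return c * (7 * r**2 - 8.75 * r**3 + 3.5 * r**5 - 0.75 * r**7)
        if self.family == "sine_hole":
            x = np.pi * h / a
            with np.errstate(invalid="ignore", divide="ignore"):
                val = c * (1.0 - np.sin(x) / x)
            return np.where(h > 0, val, 0.0)
        if self.family == "power":
            # here c is b and a is the exponent p
            return c * np.power(h, a)
        raise AssertionError(self.family)

    @property
    def has_sill(self) -> bool:
        return self.family != "power"

    def practical_range_km(self, tol: float = 0.95) -> float:
        """Distance at which the structure reaches ``tol`` of its sill."""
        if not self.has_sill or self.partial_sill == 0:
            return self.range_km
        if self.family in ("spherical", "cubic", "nugget"):
            return self.range_km
        lo, hi = 0.0, self.range_km
        target = tol * self.partial_sill
        while self.semivariance(hi) < target and hi < 1e6 * self.range_km:
            hi *= 2.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if self.semivariance(mid) < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


@dataclass
class NestedVariogramModel:
    """Nugget plus one or two theoretical structures."""

    nugget: float
    structures: tuple[VariogramStructure, ...]
    weighted_sse: float | None = None
    item: str | None = None
    detrending: str | None = None

    def __post_init__(self) -> None:
        if self.nugget < 0:
            raise VariogramError("nugget must be >= 0")
        self.structures = tuple(self.structures)
        if not 0 <= len(self.structures) <= 2:
            raise VariogramError("at most two structures in a nested model")

    def semivariance(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if np.any(h < 0):
            raise VariogramError("negative lag distance")
        out = np.where(h > 0, self.nugget, 0.0).astype(float)
        for s in self.structures:
            out = out + s.semivariance(h)
        return out

    __call__ = semivariance

    @property
    def total_sill(self) -> float | None:
        """Nugget plus partial sills; undefined (None) with a power term."""
        if any(not s.has_sill for s in self.structures):
            return None
        return self.nugget + sum(s.partial_sill for s in self.structures)

    @property
    def n_parameters(self) -> int:
        return 1 + 2 * len(self.structures)

    def practical_range_km(self) -> float:
        ranges = [s.practical_range_km() for s in self.structures if s.partial_sill > 0]
        return max(ranges) if ranges else RANGE_LOWER_BOUND_KM

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(s.family for s in self.structures)


def model_semivariance(model: NestedVariogramModel, h) -> np.ndarray:
    """gamma(h) of a nested model; h in kilometers."""
    return model.semivariance(h)


# ---------------------------------------------------------------------------
# empirical estimator


@dataclass
class EmpiricalVariogram:
    """Binned Matheron estimator: lag centers, gamma-hat and pair counts.

    Empty bins are retained with n_pairs = 0 and gamma = NaN; they are
    excluded from fitting.
    """

    lag_km: np.ndarray
    gamma: np.ndarray
    n_pairs: np.ndarray
    max_lag_km: float
    direction: tuple[float, float] | None = None  # (angle deg, tolerance deg)

    def nonempty(self):
        mask = self.n_pairs > 0
        return self.lag_km[mask], self.gamma[mask], self.n_pairs[mask]


def _pair_arrays(coords_m: np.ndarray, values: np.ndarray):
    n = len(coords_m)
    i, j = np.triu_indices(n, k=1)
    dx = coords_m[j, 0] - coords_m[i, 0]
    dy = coords_m[j, 1] - coords_m[i, 1]
    dist_km = np.hypot(dx, dy) / 1000.0
    sqdiff = (values[i] - values[j]) ** 2
    return dx, dy, dist_km, sqdiff


def empirical_semivariogram(
    coords_m: np.ndarray,
    values: np.ndarray,
    n_bins: int = 40,
    max_lag_km: float | None = None,
    direction: tuple[float, float] | None = None,
) -> EmpiricalVariogram:
    """Binned semivariogram of ``values`` at planar-meter coordinates.

    ``max_lag_km`` defaults to half the maximum pairwise distance. When
    ``direction`` = (angle, tolerance) in degrees is given, only pairs whose
    separation azimuth lies within tolerance of the angle (mod 180) enter
    the bins.
    """
    coords_m = np.asarray(coords_m, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(coords_m) < 2:
        raise VariogramError("need at least two locations")
    if len(coords_m) != len(values):
        raise VariogramError("coords and values length mismatch")

    if direction is None:
        # condensed distances only; cheaper for plain omnidirectional use
        dist_km = pdist(coords_m) / 1000.0
        sqdiff = pdist(values[:, None], metric="sqeuclidean")
    else:
        _dx, _dy, dist_km, sqdiff = _pair_arrays(coords_m, values)
        angle, tol = direction
        az = np.degrees(np.arctan2(_dy, _dx)) % 180.0
        diff = np.abs(az - angle % 180.0)
        diff = np.minimum(diff, 180.0 - diff)
        keep = diff <= tol
        dist_km, sqdiff = dist_km[keep], sqdiff[keep]

    max_pair = dist_km.max() if len(dist_km) else 0.0
    if max_lag_km is None:
        max_lag_km = max_pair / 2.0
    if max_lag_km <= 0:
        raise VariogramError("max lag must be positive")
    if max_lag_km > max_pair and max_pair > 0:
        warnings.warn("max_lag_km exceeds the maximum pairwise distance")

    edges = np.linspace(0.0, max_lag_km, n_bins + 1)
    idx = np.digitize(dist_km, edges[1:-1])
    inside = dist_km <= max_lag_km
    counts = np.bincount(idx[inside], minlength=n_bins).astype(int)
    sums = np.bincount(idx[inside], weights=sqdiff[inside], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = sums / (2.0 * counts)
    gamma[counts == 0] = np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(centers, gamma, counts, float(max_lag_km), direction)


def directional_semivariograms(
    coords_m: np.ndarray,
    values: np.ndarray,
    n_bins: int = 40,
    max_lag_km: float | None = None,
    tolerance_deg: float = 11.25,
) -> dict[float, EmpiricalVariogram]:
    """Eight directional semivariograms at 0, 22.5, ..., 157.5 degrees.

    The default half-width tolerance of 11.25 degrees partitions every pair
    into exactly one direction.
    """
    angles = [22.5 * k for k in range(8)]
    return {
        a: empirical_semivariogram(coords_m, values, n_bins, max_lag_km,
                                   direction=(a, tolerance_deg))
        for a in angles
    }


# ---------------------------------------------------------------------------
# weighted-least-squares fitting


def weighted_sse(emp: EmpiricalVariogram, model: NestedVariogramModel) -> float:
    """Cressie WLS objective: sum N(h) * (gamma_hat - gamma)^2 / gamma^2."""
    lag, gam, n = emp.nonempty()
    mod = model.semivariance(lag)
    mod = np.maximum(mod, 1e-12)
    return float(np.sum(n * (gam - mod) ** 2 / mod**2))


def _pack(nugget, structures):
    theta = [nugget]
    for s in structures:
        theta += [s.partial_sill, s.range_km]
    return np.array(theta)


def _unpack(theta, families, smoothness):
    nugget = theta[0]
    structures = []
    for k, fam in enumerate(families):
        c, a = theta[1 + 2 * k], theta[2 + 2 * k]
        structures.append(VariogramStructure(fam, c, a, smoothness[k]))
    return NestedVariogramModel(max(nugget, 0.0), tuple(structures))


def _candidate_bounds(families, max_lag, sill_scale):
    lo = [0.0]
    hi = [max(4.0 * sill_scale, 1e-6)]
    for fam in families:
        if fam == "power":
            lo += [0.0, 1e-3]
            hi += [max(10.0 * sill_scale, 1e-6), 2.0]
        else:
            lo += [0.0, RANGE_LOWER_BOUND_KM]
            hi += [max(4.0 * sill_scale, 1e-6), 4.0 * max_lag]
    return np.array(lo), np.array(hi)


def _fit_candidate(emp, families, smoothness, n_starts, rng):
    lag, gam, n = emp.nonempty()
    max_lag = lag.max()
    sill_scale = float(np.nanmean(gam[-max(len(gam) // 4, 1):]))
    lo, hi = _candidate_bounds(families, max_lag, sill_scale)

    def residuals(theta):
        model = _unpack(theta, families, smoothness)
        mod = np.maximum(model.semivariance(lag), 1e-12)
        return np.sqrt(n) * (gam - mod) / mod

    k = len(families)
    starts = []
    # method-of-moments start: nugget from the first bin, sill split evenly,
    # ranges staggered across the lag axis
    mom = [max(min(gam[0], sill_scale) * 0.5, 1e-6)]
    for s_i, fam in enumerate(families):
        if fam == "power":
            mom += [max(sill_scale / max_lag, 1e-6), 1.0]
        else:
            mom += [max(sill_scale / max(k, 1) * 0.9, 1e-6),
                    max_lag * (0.25 + 0.5 * s_i / max(k, 1))]
    starts.append(np.clip(np.array(mom), lo + 1e-12, hi - 1e-12))
    for _ in range(n_starts):
        u = rng.uniform(size=len(lo))
        start = lo + u * (np.minimum(hi, np.where(np.isfinite(hi), hi, 1.0)) - lo)
        starts.append(np.clip(start, lo + 1e-12, hi))

    best = None
    for x0 in starts:
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                max_nfev=400)
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res.x)
    if best is None:
        return None
    model = _unpack(best[1], families, smoothness)
    model.weighted_sse = weighted_sse(emp, model)
    return model


def default_candidates(
    families=("spherical", "exponential", "gaussian", "matern", "cubic",
              "sine_hole", "power"),
    nested: bool = True,
) -> list[tuple[str, ...]]:
    """All single families plus, optionally, all ordered family pairs."""
    singles = [(f,) for f in families]
    if not nested:
        return singles
    pairs = [(a, b) for a in families for b in families]
    return singles + pairs


def fit_nested_wls(
    emp: EmpiricalVariogram,
    candidates: list[tuple[str, ...]] | None = None,
    matern_smoothness_grid=MATERN_SMOOTHNESS_GRID,
    n_starts: int = 8,
    seed: int = 0,
    return_ledger: bool = False,
):
    """Fit nugget + 1-2 structure models by WLS; return the global best.

    Every candidate family tuple is optimized from a method-of-moments start
    plus ``n_starts`` seeded random starts; Matérn structures are refit for
    each smoothness on the grid. Ties break on weighted SSE then on fewer
    parameters. With ``return_ledger`` the full SSE-ranked candidate list is
    returned alongside the winner.
    """
    lag, gam, n = emp.nonempty()
    if len(lag) < 5:
        raise VariogramError("need at least 5 non-empty bins to fit")
    if candidates is None:
        candidates = default_candidates()

    rng = np.random.default_rng(seed)
    fits: list[NestedVariogramModel] = []
    for families in candidates:
        grids = [
            matern_smoothness_grid if fam == "matern" else (None,)
            for fam in families
        ]
        # cartesian product over matern smoothness options
        combos = [()]
        for g in grids:
            combos = [c + (s,) for c in combos for s in g]
        for smoothness in combos:
            model = _fit_candidate(emp, families, smoothness, n_starts, rng)
            if model is None:
                warnings.warn(f"optimizer failed for candidate {families}")
                continue
            fits.append(model)
    if not fits:
        raise VariogramError("all candidate fits failed")
    fits.sort(key=lambda m: (m.weighted_sse, m.n_parameters))
    if return_ledger:
        return fits[0], fits
    return fits[0]


# ---------------------------------------------------------------------------
# anisotropy classification


def classify_anisotropy(
    directional_models: dict[float, NestedVariogramModel],
    omni_model: NestedVariogramModel,
    rel_tol: float = 0.20,
    min_directions: int = 6,
) -> str:
    """Quantitative surrogate for the visual isotropy judgement.

    "None" when every directional fit agrees with the omnidirectional model
    in effective sill and practical range within ``rel_tol``; ">= Mid-range"
    when the directional curves track the omnidirectional curve within
    tolerance up to the omnidirectional practical range but diverge beyond
    it; otherwise "Yes (<angle>°)" naming the most deviant axis.
    Directions with too few pairs should be dropped before calling; if fewer
    than ``min_directions`` remain the label is "NA".
    """
    models = {a: m for a, m in directional_models.items() if m is not None}
    if len(models) < min_directions:
        return "NA"

    omni_sill = omni_model.total_sill
    omni_range = omni_model.practical_range_km()

    def rel(a, b):
        denom = max(abs(b), 1e-12)
        return abs(a - b) / denom

    full_ok, deviation = True, {}
    for angle, m in models.items():
        sill = m.total_sill
        if omni_sill is None or sill is None:
            sill_dev = 0.0 if (sill is None) == (omni_sill is None) else 1.0
        else:
            sill_dev = rel(sill, omni_sill)
        range_dev = rel(m.practical_range_km(), omni_range)
        deviation[angle] = max(sill_dev, range_dev)
        if deviation[angle] > rel_tol:
            full_ok = False
    if full_ok:
        return "None"

    # compare curves inside the omnidirectional range only
    h = np.linspace(omni_range / 50.0, omni_range, 50)
    omni_g = np.maximum(omni_model.semivariance(h), 1e-12)
    short_ok = True
    for angle, m in models.items():
        dev = np.max(np.abs(m.semivariance(h) - omni_g) / omni_g)
        if dev > rel_tol:
            short_ok = False
            break
    if short_ok:
        return "≥ Mid-range"
    worst = max(deviation, key=deviation.get)
    return f"Yes ({worst:g}°)"


def model_from_fixture_row(row) -> NestedVariogramModel:
    """Build a NestedVariogramModel from one packaged semivariogram-table row."""
    structures = []
    for k in (1, 2):
        fam = row.get(f"family{k}")
        if isinstance(fam, str) and fam:
            structures.append(
                VariogramStructure(fam, float(row[f"psill{k}"]),
                                   max(float(row[f"range{k}"]), RANGE_LOWER_BOUND_KM)
                                   if fam != "power" else float(row[f"range{k}"]) or 2.0)
            )
    return NestedVariogramModel(float(row["nugget"]), tuple(structures),
                                item=row.get("item"),
                                detrending=row.get("detrending"))
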