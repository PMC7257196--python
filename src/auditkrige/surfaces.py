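"""Nonparametric spatially varying probability surfaces.

Binary responses are smoothed with an isotropic Gaussian kernel
(Nadaraya-Watson ratio of weighted Yes-mass to total mass); the bandwidth
is chosen by leave-one-out likelihood cross-validation. Rendering uses a
diverging palette whose white midpoint sits at the item's overall
prevalence, so red marks above-average and blue below-average probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import nearest_neighbor_distances

_P_CLIP = 1e-6


class SurfaceError(ValueError):
    pass


def default_bandwidths(coords_m: np.ndarray, n: int = 16) -> np.ndarray:
    """Log-spaced candidates from the mean NN distance to 1/4 the extent."""
    coords_m = np.asarray(coords_m, dtype=float)
    nn = nearest_neighbor_distances(coords_m)
    lo = float(nn.mean()) if len(nn) else 1.0
    span = max(np.ptp(coords_m[:, 0]), np.ptp(coords_m[:, 1]))
    hi = max(span / 4.0, lo * 2.0)
    return np.geomspace(lo, hi, n)


def _loo_negative_likelihood(coords_m, y, bandwidth) -> float:
    d2 = ((coords_m[:, None, :] - coords_m[None, :, :]) ** 2).sum(axis=-1)
    w = np.exp(-d2 / (2.0 * bandwidth**2))
    np.fill_diagonal(w, 0.0)
    num = w @ y
    den = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = num / den
    p = np.where(den > 0, p, y.mean())
    p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
    return float(-np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def cv_bandwidth(coords_m: np.ndarray, y: np.ndarray, candidates) -> float:
    """Bandwidth minimizing the leave-one-out negative log-likelihood.

    Ties break toward the smaller bandwidth.
    """
    coords_m = np.asarray(coords_m, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(coords_m) < 10:
        raise SurfaceError("need at least 10 points for cross-validation")
    if len(np.unique(y)) < 2:
        raise SurfaceError("both response classes required")
    candidates = np.sort(np.asarray(candidates, dtype=float))
    if candidates.size == 0:
        raise SurfaceError("need at least one candidate bandwidth")
    scores = [_loo_negative_likelihood(coords_m, y, h) for h in candidates]
    if not np.isfinite(scores).any():
        raise SurfaceError("all candidate bandwidths degenerate")
    return float(candidates[int(np.nanargmin(scores))])


@dataclass
class ProbabilitySurface:
    """Gridded P(Yes) estimate with its bandwidth and render midpoint."""

    x_m: np.ndarray           # grid cell-center x coordinates
    y_m: np.ndarray           # grid cell-center y coordinates
    values: np.ndarray        # (len(y_m), len(x_m)) probabilities
    bandwidth_m: float
    prevalence: float

    def to_frame(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x_m, self.y_m)
        return pd.DataFrame({"x_m": xx.ravel(), "y_m": yy.ravel(),
                             "value": self.values.ravel()})


def probability_surface(
    coords_m: np.ndarray,
    y: np.ndarray,
    bandwidth_m: float,
    extent: tuple[float, float, float, float] | None = None,
    resolution_m: float = 250.0,
    min_total_weight: float = 1e-3,
) -> ProbabilitySurface:
    """Kernel-smoothed P(Yes) on a regular grid.

    Cells whose total kernel weight falls below ``min_total_weight`` (in
    units of point mass) revert to the overall prevalence.
    """
    coords_m = np.asarray(coords_m, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(coords_m) == 0:
        raise SurfaceError("empty point set")
    if bandwidth_m <= 0:
        raise SurfaceError("bandwidth must be positive")
    if extent is None:
        extent = (coords_m[:, 0].min(), coords_m[:, 1].min(),
                  coords_m[:, 0].max(), coords_m[:, 1].max())
    xmin, ymin, xmax, ymax = extent
    xs = np.arange(xmin + resolution_m / 2, xmax, resolution_m)
    ys = np.arange(ymin + resolution_m / 2, ymax, resolution_m)
    prevalence = float(y.mean())
    values = np.empty((len(ys), len(xs)))
    for i, gy in enumerate(ys):
        d2 = ((coords_m[:, 0][None, :] - xs[:, None]) ** 2
              + (coords_m[:, 1] - gy) ** 2)
        w = np.exp(-d2 / (2.0 * bandwidth_m**2))
        den = w.sum(axis=1)
        num = w @ y
        with np.errstate(invalid="ignore", divide="ignore"):
            p = num / den
        values[i] = np.where(den >= min_total_weight, p, prevalence)
    return ProbabilitySurface(xs, ys, values, float(bandwidth_m), prevalence)


def render_divergent(surface: ProbabilitySurface, path=None, ax=None):
    """Diverging red/white/blue raster centered at the item prevalence."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm

    mid = min(max(surface.prevalence, 1e-6), 1 - 1e-6)
    norm = TwoSlopeNorm(vmin=0.0, vcenter=mid, vmax=1.0)
    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(7, 4))
    else:
        fig = ax.figure
    im = ax.imshow(
        surface.values, origin="lower", cmap="RdBu_r", norm=norm,
        extent=(surface.x_m[0], surface.x_m[-1], surface.y_m[0], surface.y_m[-1]),
        aspect="equal",
    )
    cbar = fig.colorbar(im, ax=ax, shrink=0.8)
    cbar.set_label(f"P(Yes); white = prevalence {surface.prevalence:.3f}")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
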