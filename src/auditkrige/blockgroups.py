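"""Block-group-level correlation of predicted audit responses with
census-style covariates.

Item responses are predicted at k random locations per areal unit; the k
unit-level values are treated as multiple imputations and Pearson
correlations are pooled by Rubin's rules on the Fisher-z scale (mean of
per-imputation z; total variance = within + (1 + 1/m) * between), then
back-transformed to r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audit_io import BlockGroupLayer


class BlockGroupError(ValueError):
    pass


def sample_prediction_points(
    layer: BlockGroupLayer,
    k: int = 10,
    seed: int = 0,
    max_tries: int = 10_000,
) -> pd.DataFrame:
    """Exactly k uniform points inside every unit polygon.

    Rejection sampling against each polygon's bounding box; reproducible
    under the seed. Returns columns unit_id, imputation (1..k), x_m, y_m.
    """
    from shapely.geometry import Point

    rng = np.random.default_rng(seed)
    rows = []
    for unit_id, poly in zip(layer.table["unit_id"], layer.polygons):
        xmin, ymin, xmax, ymax = poly.bounds
        got = 0
        tries = 0
        while got < k:
            if tries >= max_tries:
                raise BlockGroupError(
                    f"rejection sampling failed for unit {unit_id} "
                    f"after {max_tries} tries (degenerate polygon?)"
                )
            x = rng.uniform(xmin, xmax)
            y = rng.uniform(ymin, ymax)
            tries += 1
            if poly.contains(Point(x, y)):
                got += 1
                rows.append((unit_id, got, x, y))
    return pd.DataFrame(rows, columns=["unit_id", "imputation", "x_m", "y_m"])


@dataclass
class PooledCorrelation:
    """Rubin-pooled Pearson correlation for one variable pair."""

    var_a: str
    var_b: str
    r: float
    within_variance: float
    between_variance: float
    total_variance: float
    m: int


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def pooled_correlation(
    table: pd.DataFrame,
    var_a: str,
    var_b: str,
) -> PooledCorrelation:
    """Rubin's-rules pooling of per-imputation Pearson correlations.

    ``table`` has columns unit_id, imputation and the two variables; the
    correlation is computed across units within each imputation, pooled on
    the Fisher-z scale. Covariates constant across imputations are fine.
    An imputation with zero variance in either variable is undefined; more
    than half undefined is an error.
    """
    imps = sorted(table["imputation"].unique())
    m = len(imps)
    if m < 2:
        raise BlockGroupError("need at least 2 imputations")
    zs, n_units = [], None
    undefined = 0
    for imp in imps:
        sub = table[table["imputation"] == imp]
        a = sub[var_a].to_numpy(dtype=float)
        b = sub[var_b].to_numpy(dtype=float)
        if len(a) < 3:
            raise BlockGroupError("need at least 3 units")
        n_units = len(a)
        if a.std() == 0 or b.std() == 0:
            undefined += 1
            continue
        zs.append(float(_fisher_z(np.corrcoef(a, b)[0, 1])))
    if undefined > m / 2:
        raise BlockGroupError(
            f"{undefined}/{m} imputations have zero variance in "
            f"({var_a!r}, {var_b!r})"
        )
    zs = np.asarray(zs)
    m_eff = len(zs)
    z_bar = float(zs.mean())
    within = 1.0 / max(n_units - 3, 1)  # large-sample var of Fisher z
    between = float(zs.var(ddof=1)) if m_eff > 1 else 0.0
    total = within + (1.0 + 1.0 / m_eff) * between
    return PooledCorrelation(var_a, var_b, float(np.tanh(z_bar)),
                             within, between, total, m_eff)


def correlation_matrix(
    table: pd.DataFrame,
    variables: list[str],
    flag_threshold: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric pooled-correlation matrix with |r| > threshold flags.

    Returns (r_matrix, flag_matrix) as DataFrames indexed by variable.
    """
    if len(variables) < 2:
        raise BlockGroupError("need at least 2 variables")
    k = len(variables)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            pc = pooled_correlation(table, variables[i], variables[j])
            r[i, j] = r[j, i] = pc.r
    rm = pd.DataFrame(r, index=variables, columns=variables)
    flags = rm.abs().gt(flag_threshold) & ~np.eye(k, dtype=bool)
    return rm, pd.DataFrame(flags, index=variables, columns=variables)


def render_heatmap(r_matrix: pd.DataFrame, path=None):
    """Divergent heatmap of a pooled-correlation matrix."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.5 * len(r_matrix) + 3,) * 2)
    im = ax.imshow(r_matrix.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(r_matrix)), r_matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(r_matrix)), r_matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8, label="pooled r")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
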