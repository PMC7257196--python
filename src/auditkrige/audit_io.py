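"""Reading and writing of audit point tables, block-group layers and the
packaged reference tables.

Coordinates are planar meters in an equidistant projection; the package
never reprojects. Audit responses are stored on disk in the survey coding
1 = "Yes" / 2 = "No" (missing allowed where an item was not applicable);
``analysis_frame`` recodes to y in {1, 0} at the analysis boundary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

ITEM_PREFIX = "item_"

#: survey coding on disk -> analysis coding
RESPONSE_CODES = {1: 1, 2: 0}

_FIXTURE_FILES = {
    1: "table1_prevalence.csv",
    2: "table2_semivariograms.csv",
    3: "table3_auc.csv",
}


class AuditIOError(ValueError):
    """Invalid audit table or fixture content."""


@dataclass
class AuditDataset:
    """Audit locations with coordinates, rater and binary item responses.

    ``frame`` holds one row per audit location with columns ``id``, ``x_m``,
    ``y_m``, ``rater`` and one ``item_<name>`` column per audit item coded
    {1, 2} (NaN where the item was not applicable at that location).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "x_m", "y_m", "rater"}
        missing = required - set(self.frame.columns)
        if missing:
            raise AuditIOError(f"audit table missing columns: {sorted(missing)}")
        if self.frame["id"].duplicated().any():
            dupes = self.frame.loc[self.frame["id"].duplicated(), "id"].tolist()
            raise AuditIOError(f"duplicate location ids: {dupes[:10]}")
        coords = self.frame[["x_m", "y_m"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise AuditIOError("non-finite coordinates in audit table")
        for col in self.item_columns:
            vals = self.frame[col].dropna().unique()
            bad = sorted(set(vals) - set(RESPONSE_CODES))
            if bad:
                rows = self.frame.index[self.frame[col].isin(bad)].tolist()
                raise AuditIOError(
                    f"unknown response codes {bad} in column {col!r}, rows {rows[:10]}"
                )

    @property
    def item_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith(ITEM_PREFIX)]

    @property
    def items(self) -> list[str]:
        return [c[len(ITEM_PREFIX):] for c in self.item_columns]

    @property
    def n(self) -> int:
        return len(self.frame)

    def coords(self) -> np.ndarray:
        """(n, 2) array of x/y in meters."""
        return self.frame[["x_m", "y_m"]].to_numpy(dtype=float)

    def analysis_frame(self, item: str) -> pd.DataFrame:
        """Per-item modeling table with y recoded 1=Yes, 0=No.

        Locations where the item response is missing (item not applicable)
        are dropped, mirroring the per-item denominators of the survey.
        """
        col = ITEM_PREFIX + item
        if col not in self.frame.columns:
            raise KeyError(f"unknown audit item {item!r}")
        sub = self.frame.loc[self.frame[col].notna(), ["id", "x_m", "y_m", "rater", col]]
        out = sub.rename(columns={col: "y"}).copy()
        out["y"] = out["y"].map(RESPONSE_CODES).astype(int)
        return out.reset_index(drop=True)


def read_audit_csv(path: str | Path) -> AuditDataset:
    """Read a UTF-8 comma-separated audit point table."""
    frame = pd.read_csv(path)
    return AuditDataset(frame)


def write_audit_csv(dataset: AuditDataset, path: str | Path) -> None:
    dataset.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# packaged reference tables


def _fixture_path(name: str):
    return resources.files("auditkrige.data").joinpath(name)


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def load_published_table(table_id: int, verify: bool = True) -> pd.DataFrame:
    """Load one of the packaged published-results tables (1, 2 or 3).

    Table 1: per-item prevalence; table 2: fitted nested-semivariogram
    parameters, RMSPE and anisotropy labels; table 3: ROC AUC of the
    large-scale-only and full (Kriging) models with percent changes.
    Fixture bytes are checked against a packaged SHA-256 checksum.
    """
    if table_id not in _FIXTURE_FILES:
        raise AuditIOError(f"unknown fixture table id {table_id!r}; expected 1, 2 or 3")
    name = _FIXTURE_FILES[table_id]
    ref = _fixture_path(name)
    raw = ref.read_bytes()
    if verify:
        sums = json.loads(_fixture_path("checksums.json").read_text())
        if _sha256(raw) != sums[name]:
            raise AuditIOError(f"checksum mismatch for fixture {name}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def evaluation_table_from_fixtures() -> pd.DataFrame:
    """Merge the packaged semivariogram and AUC tables into one evaluation table.

    One row per item x detrending variant, carrying the nugget, RMSPE and
    RMSPE percent change alongside the AUC columns and the item family.
    """
    t1 = load_published_table(1)
    t2 = load_published_table(2)
    t3 = load_published_table(3)
    merged = t3.merge(
        t2[["item", "detrending", "nugget", "rmspe", "pct_rmspe_change"]],
        on=["item", "detrending"],
        how="left",
    ).merge(t1[["item", "group"]], on="item", how="left")
    return merged


# ---------------------------------------------------------------------------
# block-group layers (GeoJSON polygons + covariate table)


@dataclass
class BlockGroupLayer:
    """Census-like areal units tiling the study extent.

    ``polygons`` are shapely Polygons indexed by ``unit_id`` order in
    ``table``; ``table`` carries one row per unit with the covariates.
    """

    polygons: list = field(repr=False)
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.polygons) != len(self.table):
            raise AuditIOError("polygon count does not match covariate table")
        numeric = self.table.select_dtypes("number")
        if not np.isfinite(numeric.to_numpy(dtype=float)).all():
            raise AuditIOError("non-finite covariate values")

    @property
    def n_units(self) -> int:
        return len(self.polygons)

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.table.columns if c != "unit_id"]


def write_block_groups(layer: BlockGroupLayer, geojson_path: str | Path,
                       covariates_path: str | Path) -> None:
    from shapely.geometry import mapping

    features = []
    for poly, (_, row) in zip(layer.polygons, layer.table.iterrows()):
        features.append({
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"unit_id": int(row["unit_id"])},
        })
    Path(geojson_path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
    layer.table.to_csv(covariates_path, index=False)


def read_block_groups(geojson_path: str | Path,
                      covariates_path: str | Path) -> BlockGroupLayer:
    from shapely.geometry import shape

    gj = json.loads(Path(geojson_path).read_text())
    feats = sorted(gj["features"], key=lambda f: f["properties"]["unit_id"])
    polygons = [shape(f["geometry"]) for f in feats]
    table = pd.read_csv(covariates_path).sort_values("unit_id").reset_index(drop=True)
    return BlockGroupLayer(polygons, table)


def read_config(path: str | Path) -> dict:
    """Read a run-configuration JSON file."""
    return json.loads(Path(path).read_text())
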