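"""Reading jurisdictional-unit geometries and attribute tables.

A *unit* is one de jure administrative area (province, district, ward, ...)
carrying the raw quantities the analysis consumes: total area, forest and
potential-forest area, population, road length, flat-terrain area, crop
suitability and (where available) cereal yield.

Vector input formats: GeoJSON, GeoPackage (read through sqlite3 + WKB) and
CSV with a WKT geometry column.  Attribute tables: CSV or Excel.  All areas
are carried in hectares.
"""

from __future__ import annotations

import json
import logging
import sqlite3
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import shapely.wkt
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from . import crs

logger = logging.getLogger(__name__)

COUNTRIES = ("ZAM", "ECU", "PHI")
COUNTRY_SCOPES = COUNTRIES + ("PAN",)
LEVELS = ("macro", "meso", "micro")

#: raw attribute columns expected on ingest (CY optional)
RAW_FIELDS = ("A_TOT", "FA", "FA_pot", "P_TOT", "R_TOT", "FL_TOT", "CSI", "CY")


@dataclass(frozen=True)
class SampleId:
    """One of the twelve (country-scope, level) samples."""

    country_scope: str
    level: str

    def __post_init__(self):
        if self.country_scope not in COUNTRY_SCOPES:
            raise ValueError(f"unknown country scope {self.country_scope!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")

    def __str__(self) -> str:
        return f"{self.country_scope}:{self.level}"

    @classmethod
    def parse(cls, text: str) -> "SampleId":
        country, _, level = text.partition(":")
        return cls(country.strip().upper(), level.strip().lower())


ALL_SAMPLES = tuple(
    SampleId(c, l) for c in COUNTRY_SCOPES for l in LEVELS
)


@dataclass
class UnitRecord:
    """One jurisdictional unit with geometry reference and raw attributes.

    Areas in hectares, population in persons, road length in kilometres,
    CSI on the 0-100 index scale, CY in kcal/ha (None when the sample has
    no cereal-yield information).
    """

    unit_id: str
    country: str
    level: str
    A_TOT: float
    FA: float
    FA_pot: float
    P_TOT: float
    R_TOT: float
    FL_TOT: float
    CSI: float
    CY: float | None = None
    centroid: tuple[float, float] | None = None  # projected metres
    lonlat: tuple[float, float] | None = None  # geographic centroid
    geometry: BaseGeometry | None = field(default=None, repr=False)

    def validate(self) -> None:
        if self.country not in COUNTRIES:
            raise ValueError(f"{self.unit_id}: unknown country {self.country!r}")
        if self.level not in LEVELS:
            raise ValueError(f"{self.unit_id}: unknown level {self.level!r}")
        if not (0.0 <= self.FA <= self.FA_pot <= self.A_TOT):
            raise ValueError(
                f"{self.unit_id}: need 0 <= FA <= FA_pot <= A_TOT, got "
                f"FA={self.FA}, FA_pot={self.FA_pot}, A_TOT={self.A_TOT}"
            )
        if not 0.0 <= self.CSI <= 100.0:
            raise ValueError(f"{self.unit_id}: CSI {self.CSI} outside [0, 100]")
        if self.centroid is not None and not np.all(np.isfinite(self.centroid)):
            raise ValueError(f"{self.unit_id}: non-finite centroid")


# ---------------------------------------------------------------------------
# vector / tabular readers

def _read_geojson(path: Path) -> list[tuple[dict, BaseGeometry]]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return [
        (feat.get("properties") or {}, shapely_shape(feat["geometry"]))
        for feat in doc["features"]
    ]


def _read_wkt_csv(path: Path, geometry_column: str = "geometry"
                  ) -> list[tuple[dict, BaseGeometry]]:
    df = pd.read_csv(path)
    if geometry_column not in df.columns:
        raise ValueError(f"{path}: no {geometry_column!r} column")
    out = []
    for _, row in df.iterrows():
        props = row.drop(geometry_column).to_dict()
        out.append((props, shapely.wkt.loads(row[geometry_column])))
    return out


def _gpkg_geometry(blob: bytes) -> BaseGeometry:
    # GeoPackage geometry = 8-byte header (+ optional envelope) + ISO WKB
    if blob[:2] != b"GP":
        raise ValueError("not a GeoPackage geometry blob")
    flags = blob[3]
    envelope_code = (flags >> 1) & 0b111
    envelope_len = {0: 0, 1: 32, 2: 48, 3: 48, 4: 64}[envelope_code]
    return shapely.from_wkb(blob[8 + envelope_len:])


def _read_gpkg(path: Path, layer: str | None = None
               ) -> list[tuple[dict, BaseGeometry]]:
    con = sqlite3.connect(path)
    try:
        contents = pd.read_sql(
            "SELECT table_name FROM gpkg_contents WHERE data_type='features'",
            con,
        )
        if layer is None:
            if len(contents) != 1:
                raise ValueError(
                    f"{path}: specify a layer, found {list(contents.table_name)}"
                )
            layer = contents.table_name.iloc[0]
        geom_col = pd.read_sql(
            "SELECT column_name FROM gpkg_geometry_columns WHERE table_name=?",
            con, params=(layer,),
        ).column_name.iloc[0]
        df = pd.read_sql(f'SELECT * FROM "{layer}"', con)
    finally:
        con.close()
    out = []
    for _, row in df.iterrows():
        props = row.drop([geom_col]).to_dict()
        out.append((props, _gpkg_geometry(row[geom_col])))
    return out


def read_boundaries(path: str | Path, layer: str | None = None
                    ) -> list[tuple[dict, BaseGeometry]]:
    """Read (properties, geometry) pairs from GeoJSON / GeoPackage / WKT-CSV."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".geojson", ".json"):
        return _read_geojson(path)
    if suffix == ".gpkg":
        return _read_gpkg(path, layer)
    if suffix == ".csv":
        return _read_wkt_csv(path)
    raise ValueError(f"unsupported boundary format: {path.name}")


def read_attributes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path, float_precision="round_trip")
    raise ValueError(f"unsupported attribute format: {path.name}")


def read_units(
    boundary_path: str | Path,
    attribute_path: str | Path,
    join_key: str,
    country: str | None = None,
    level: str | None = None,
    layer: str | None = None,
) -> tuple[list[UnitRecord], pd.DataFrame]:
    """Join boundary geometries to an attribute table on ``join_key``.

    Returns the matched units plus a rejects table listing attribute rows
    with no polygon and polygons with no attribute row.  Duplicate join
    keys on either side are a hard error.
    """
    features = read_boundaries(boundary_path, layer=layer)
    attrs = read_attributes(attribute_path)
    if join_key not in attrs.columns:
        raise ValueError(f"attribute table lacks join key {join_key!r}")
    if attrs[join_key].duplicated().any():
        dupes = attrs.loc[attrs[join_key].duplicated(), join_key].tolist()
        raise ValueError(f"duplicate join keys in attribute table: {dupes}")

    geom_by_key: dict[str, BaseGeometry] = {}
    for props, geom in features:
        if join_key not in props:
            raise ValueError(f"boundary feature lacks join key {join_key!r}")
        key = str(props[join_key])
        if key in geom_by_key:
            raise ValueError(f"duplicate join key in boundaries: {key!r}")
        geom_by_key[key] = geom

    units: list[UnitRecord] = []
    rejects: list[dict] = []
    attr_keys = set()
    for _, row in attrs.iterrows():
        key = str(row[join_key])
        attr_keys.add(key)
        if key not in geom_by_key:
            rejects.append({"unit_id": key, "reason": "no matching polygon"})
            continue
        cy = row.get("CY", np.nan)
        units.append(UnitRecord(
            unit_id=key,
            country=str(row.get("country", country)),
            level=str(row.get("level", level)),
            A_TOT=float(row["A_TOT"]),
            FA=float(row["FA"]),
            FA_pot=float(row["FA_pot"]),
            P_TOT=float(row["P_TOT"]),
            R_TOT=float(row["R_TOT"]),
            FL_TOT=float(row["FL_TOT"]),
            CSI=float(row["CSI"]),
            CY=None if pd.isna(cy) else float(cy),
            geometry=geom_by_key[key],
        ))
    for key in geom_by_key:
        if key not in attr_keys:
            rejects.append({"unit_id": key, "reason": "no matching attribute row"})
    rejects_df = pd.DataFrame(rejects, columns=["unit_id", "reason"])
    if len(rejects_df):
        logger.warning("read_units: %d unmatched records", len(rejects_df))
    return units, rejects_df


# ---------------------------------------------------------------------------
# projection and measurement

def project_and_measure(
    units: Sequence[UnitRecord],
    crs_spec: str | None = None,
    set_area: bool = False,
) -> list[UnitRecord]:
    """Project geographic geometries to UTM; compute centroids and areas.

    ``crs_spec`` is a zone like ``"35S"``; when None each unit's country
    default is used.  Geometries must carry WGS84 lon/lat coordinates.
    With ``set_area`` the measured polygon area [ha] overwrites A_TOT.
    """
    out = []
    for unit in units:
        if unit.geometry is None:
            raise ValueError(f"{unit.unit_id}: no geometry to project")
        zone = crs.parse_zone(crs_spec) if crs_spec else crs.zone_for_country(unit.country)
        geographic_centroid = unit.geometry.centroid
        projected = shapely.transform(
            unit.geometry,
            lambda coords: np.column_stack(
                crs.geographic_to_utm(coords[:, 0], coords[:, 1], zone)
            ),
        )
        area_ha = projected.area / 10_000.0
        if area_ha <= 0.0:
            raise ValueError(f"{unit.unit_id}: degenerate zero-area geometry")
        c = projected.centroid
        out.append(replace(
            unit,
            centroid=(c.x, c.y),
            lonlat=(geographic_centroid.x, geographic_centroid.y),
            geometry=projected,
            A_TOT=area_ha if set_area else unit.A_TOT,
        ))
    return out


def area_weighted_mean(values: Iterable[tuple[float, float]]) -> float:
    """Mean of ``(value, area)`` pairs weighted by area: sum(v*a)/sum(a)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected (value, area) pairs")
    v, a = arr[:, 0], arr[:, 1]
    if np.any(a < 0):
        raise ValueError("negative areas")
    total = a.sum()
    if total <= 0:
        raise ValueError("no positive areas")
    return float(np.dot(v, a) / total)


# ---------------------------------------------------------------------------
# tabular serialization

_TABLE_COLUMNS = [
    "unit_id", "country", "level", "A_TOT", "FA", "FA_pot", "P_TOT",
    "R_TOT", "FL_TOT", "CSI", "CY", "centroid_x", "centroid_y",
    "lon", "lat",
]


def units_to_frame(units: Sequence[UnitRecord]) -> pd.DataFrame:
    rows = []
    for u in units:
        rows.append({
            "unit_id": u.unit_id, "country": u.country, "level": u.level,
            "A_TOT": u.A_TOT, "FA": u.FA, "FA_pot": u.FA_pot,
            "P_TOT": u.P_TOT, "R_TOT": u.R_TOT, "FL_TOT": u.FL_TOT,
            "CSI": u.CSI, "CY": np.nan if u.CY is None else u.CY,
            "centroid_x": np.nan if u.centroid is None else u.centroid[0],
            "centroid_y": np.nan if u.centroid is None else u.centroid[1],
            "lon": np.nan if u.lonlat is None else u.lonlat[0],
            "lat": np.nan if u.lonlat is None else u.lonlat[1],
        })
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def frame_to_units(df: pd.DataFrame) -> list[UnitRecord]:
    units = []
    for _, row in df.iterrows():
        centroid = None
        if not pd.isna(row.get("centroid_x", np.nan)):
            centroid = (float(row["centroid_x"]), float(row["centroid_y"]))
        lonlat = None
        if not pd.isna(row.get("lon", np.nan)):
            lonlat = (float(row["lon"]), float(row["lat"]))
        cy = row.get("CY", np.nan)
        units.append(UnitRecord(
            unit_id=str(row["unit_id"]), country=str(row["country"]),
            level=str(row["level"]), A_TOT=float(row["A_TOT"]),
            FA=float(row["FA"]), FA_pot=float(row["FA_pot"]),
            P_TOT=float(row["P_TOT"]), R_TOT=float(row["R_TOT"]),
            FL_TOT=float(row["FL_TOT"]), CSI=float(row["CSI"]),
            CY=None if pd.isna(cy) else float(cy),
            centroid=centroid, lonlat=lonlat,
        ))
    return units


def write_units(units: Sequence[UnitRecord], path: str | Path) -> None:
    # %.17g guarantees binary round-trip of doubles through the CSV
    units_to_frame(units).to_csv(path, index=False, float_format="%.17g")


def read_unit_table(path: str | Path) -> list[UnitRecord]:
    return frame_to_units(pd.read_csv(path, float_precision="round_trip"))


def write_units_geojson(units: Sequence[UnitRecord], path: str | Path) -> None:
    """Write units with geometries as a GeoJSON FeatureCollection."""
    features = []
    for u in units:
        if u.geometry is None:
            raise ValueError(f"{u.unit_id}: no geometry to write")
        props = {
            "unit_id": u.unit_id, "country": u.country, "level": u.level,
            "A_TOT": u.A_TOT, "FA": u.FA, "FA_pot": u.FA_pot,
            "P_TOT": u.P_TOT, "R_TOT": u.R_TOT, "FL_TOT": u.FL_TOT,
            "CSI": u.CSI,
        }
        if u.CY is not None:
            props["CY"] = u.CY
        features.append({
            "type": "Feature",
            "properties": props,
            "geometry": json.loads(shapely.to_geojson(u.geometry)),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
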