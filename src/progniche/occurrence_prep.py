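"""Occurrence cleaning: dedupe, seasonal windows, M-clipping, spatial rarefaction.

Raw point records (GBIF/DarwinCore-style tables) are reduced to
analysis-ready, per-taxon presence sets: exact coordinate duplicates are
collapsed, records are restricted to the breeding season of the taxon's
hemisphere, points outside the taxon's accessible area (M) are split off as
outliers, and the remainder is thinned so that no two retained localities lie
within a minimum great-circle distance of one another (20 km by default).
Every filter appends a step to the set's provenance ledger so the chain of
counts can be reproduced exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_KM = 6371.0

#: months of the Northern-Hemisphere breeding window
NORTH_BREEDING_MONTHS = frozenset({4, 5, 6, 7})
#: months of the Southern-Hemisphere breeding window
SOUTH_BREEDING_MONTHS = frozenset({10, 11, 12, 1})

RECORD_COLUMNS = ["taxon", "lon", "lat", "year", "month", "day", "source_id"]

# DarwinCore-style header aliases accepted on read
_COLUMN_ALIASES = {
    "decimallongitude": "lon",
    "longitude": "lon",
    "lon": "lon",
    "decimallatitude": "lat",
    "latitude": "lat",
    "lat": "lat",
    "species": "taxon",
    "taxon": "taxon",
    "scientificname": "taxon",
    "year": "year",
    "month": "month",
    "day": "day",
    "source_id": "source_id",
    "gbifid": "source_id",
}


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    bad_lon = (df["lon"] < -180) | (df["lon"] > 180)
    bad_lat = (df["lat"] < -90) | (df["lat"] > 90)
    if bad_lon.any() or bad_lat.any():
        raise ValueError(
            f"{int(bad_lon.sum())} records with longitude outside [-180, 180], "
            f"{int(bad_lat.sum())} with latitude outside [-90, 90]"
        )
    if "month" in df:
        m = df["month"].dropna()
        if ((m < 1) | (m > 12)).any():
            raise ValueError("month values must lie in 1-12")
    return df


@dataclass
class OccurrenceSet:
    """Cleaned point records for one taxon (or population).

    ``records`` is a DataFrame with columns ``lon, lat, year, month, day,
    source_id`` (calendar fields may be NA); ``provenance`` is the ordered
    list of applied filters with input/output counts.
    """

    taxon: str
    records: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        for col in ("lon", "lat"):
            if col not in self.records.columns:
                raise ValueError(f"records missing required column {col!r}")
        for col in ("year", "month", "day", "source_id"):
            if col not in self.records.columns:
                self.records[col] = pd.NA
        _validate_records(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def _step(self, name: str, result: pd.DataFrame, **extra) -> "OccurrenceSet":
        entry = {"step": name, "n_in": len(self.records), "n_out": len(result), **extra}
        return OccurrenceSet(self.taxon, result.reset_index(drop=True), self.provenance + [entry])

    @property
    def lonlat(self) -> np.ndarray:
        return self.records[["lon", "lat"]].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        out = self.records.rename(columns={"lon": "decimalLongitude", "lat": "decimalLatitude"})
        out.insert(0, "taxon", self.taxon)
        out.to_csv(path, index=False)

    def write_provenance(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"taxon": self.taxon, "filters": self.provenance}, fh, indent=2)


@dataclass(frozen=True)
class AccessibleArea:
    """A taxon's accessible area M: one or more simple polygons (WGS84).

    Ms delimit the region the taxon could plausibly have reached; they serve
    as the calibration region for niche models and for flagging erroneous
    records. Points on a polygon boundary count as inside.
    """

    taxon: str
    polygons: tuple[BaseGeometry, ...]

    def __post_init__(self):
        if not self.polygons:
            raise ValueError("AccessibleArea requires at least one polygon")
        for p in self.polygons:
            if p.is_empty:
                raise ValueError(f"empty polygon in M for {self.taxon!r}")
            if not p.is_valid:
                raise ValueError(f"invalid (self-intersecting) polygon in M for {self.taxon!r}")

    @property
    def geometry(self) -> BaseGeometry:
        return shapely.union_all(list(self.polygons))

    def covers_xy(self, lons, lats) -> np.ndarray:
        """Boundary-inclusive point-in-M test, vectorized."""
        return shapely.intersects_xy(self.geometry, np.asarray(lons), np.asarray(lats))

    def contains_xy(self, lons, lats) -> np.ndarray:
        """Interior-only point-in-M test (boundary excluded)."""
        geom = self.geometry
        return shapely.contains_xy(geom, np.asarray(lons), np.asarray(lats))

    def to_geojson_feature(self) -> dict:
        return {
            "type": "Feature",
            "properties": {"taxon": self.taxon},
            "geometry": mapping(self.geometry),
        }


def write_accessible_areas(areas, path) -> None:
    fc = {"type": "FeatureCollection", "features": [a.to_geojson_feature() for a in areas]}
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_accessible_areas(path) -> list[AccessibleArea]:
    with open(path) as fh:
        fc = json.load(fh)
    areas = []
    for feat in fc["features"]:
        geom = shape(feat["geometry"])
        polys = tuple(geom.geoms) if geom.geom_type == "MultiPolygon" else (geom,)
        areas.append(AccessibleArea(feat["properties"]["taxon"], polys))
    return areas


@dataclass(frozen=True)
class SeasonWindow:
    """Set of calendar months defining the breeding season to retain."""

    months: frozenset

    def __post_init__(self):
        if not self.months:
            raise ValueError("SeasonWindow requires at least one month")
        if not all(1 <= m <= 12 for m in self.months):
            raise ValueError("months must lie in 1-12")

    @classmethod
    def northern(cls) -> "SeasonWindow":
        return cls(NORTH_BREEDING_MONTHS)

    @classmethod
    def southern(cls) -> "SeasonWindow":
        return cls(SOUTH_BREEDING_MONTHS)

    @classmethod
    def auto(cls, occ: OccurrenceSet) -> "SeasonWindow":
        """Hemisphere rule: median latitude of the records decides the window."""
        med = float(np.median(occ.records["lat"])) if len(occ) else 0.0
        return cls.northern() if med >= 0 else cls.southern()


def read_occurrences(path) -> pd.DataFrame:
    """Read an occurrence CSV, accepting DarwinCore-style or plain headers."""
    df = pd.read_csv(path)
    renames = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _COLUMN_ALIASES:
            renames[col] = _COLUMN_ALIASES[key]
    df = df.rename(columns=renames)
    missing = {"taxon", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
    for col in ("year", "month", "day", "source_id"):
        if col not in df.columns:
            df[col] = pd.NA
    return _validate_records(df[RECORD_COLUMNS])


def split_by_taxon(df: pd.DataFrame) -> dict:
    return {
        taxon: OccurrenceSet(taxon, grp.drop(columns="taxon").reset_index(drop=True))
        for taxon, grp in df.groupby("taxon", sort=True)
    }


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def dedupe(occ: OccurrenceSet) -> OccurrenceSet:
    """Collapse exact coordinate duplicates, keeping the first-seen record."""
    if len(occ) == 0:
        warnings.warn(f"dedupe: empty occurrence set for {occ.taxon!r}")
        return occ._step("dedupe", occ.records)
    kept = occ.records.drop_duplicates(subset=["lon", "lat"], keep="first")
    return occ._step("dedupe", kept)


def season_filter(occ: OccurrenceSet, window: SeasonWindow | None = None,
                  drop_undated: bool = True) -> OccurrenceSet:
    """Keep records whose month falls in the breeding window.

    ``window=None`` applies the hemisphere rule (April-July north of the
    equator, October-January south). Records lacking a month are dropped when
    ``drop_undated`` (the default for migratory taxa) and kept otherwise.
    """
    if window is None:
        window = SeasonWindow.auto(occ)
    months = occ.records["month"]
    has_month = months.notna()
    in_window = has_month & months.isin(list(window.months))
    keep = in_window | (~has_month & ~drop_undated)
    return occ._step("season_filter", occ.records[keep],
                     months=sorted(window.months), drop_undated=drop_undated)


def clip_to_m(occ: OccurrenceSet, m: AccessibleArea) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Split records into (inside-M, outliers); boundary points count inside."""
    inside = m.covers_xy(occ.records["lon"].to_numpy(), occ.records["lat"].to_numpy())
    kept = occ._step("clip_to_m", occ.records[inside], m_taxon=m.taxon)
    outliers = OccurrenceSet(occ.taxon, occ.records[~inside].reset_index(drop=True),
                             occ.provenance + [{"step": "clip_to_m_outliers",
                                                "n_in": len(occ), "n_out": int((~inside).sum())}])
    return kept, outliers


def rarefy(occ: OccurrenceSet, min_km: float = 20.0, presort: bool = True) -> OccurrenceSet:
    """Greedy spatial thinning: retained localities are pairwise >= min_km apart.

    Records are visited in input order (after a canonical sort by (lon, lat)
    when ``presort``); a record is kept iff it lies at least ``min_km`` (great
    circle, haversine) from every already-kept record. Deterministic for a
    fixed input order, and idempotent.
    """
    if min_km <= 0:
        raise ValueError("min_km must be positive")
    df = occ.records
    if presort:
        df = df.sort_values(["lon", "lat"], kind="mergesort")
    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)
    kept_idx: list[int] = []
    for i in range(len(df)):
        if not kept_idx:
            kept_idx.append(i)
            continue
        d = haversine_km(lon[i], lat[i], lon[kept_idx], lat[kept_idx])
        if np.all(d >= min_km):
            kept_idx.append(i)
    return occ._step("rarefy", df.iloc[kept_idx], min_km=min_km)


def assign_population(occ: OccurrenceSet, ms: list[AccessibleArea]) -> tuple[dict, OccurrenceSet]:
    """Assign each record to the unique population M containing it.

    Population Ms must be pairwise interior-disjoint; a record lying in two
    interiors raises an error naming the polygons. Returns
    (population -> OccurrenceSet, unassigned records). A record on a shared
    boundary is assigned to the first matching M in list order.
    """
    lons = occ.records["lon"].to_numpy()
    lats = occ.records["lat"].to_numpy()
    interior = np.stack([m.contains_xy(lons, lats) for m in ms])  # (n_ms, n_rec)
    multi = interior.sum(axis=0) > 1
    if multi.any():
        i = int(np.argmax(multi))
        names = [m.taxon for k, m in enumerate(ms) if interior[k, i]]
        raise ValueError(
            f"record at ({lons[i]:.4f}, {lats[i]:.4f}) lies inside the interiors of "
            f"multiple population Ms: {names}"
        )
    covers = np.stack([m.covers_xy(lons, lats) for m in ms])
    assigned_to = np.full(len(occ), -1, dtype=int)
    for k in range(len(ms)):
        free = (assigned_to < 0) & covers[k]
        assigned_to[free] = k
    out = {}
    for k, m in enumerate(ms):
        sub = occ.records[assigned_to == k].reset_index(drop=True)
        prov = occ.provenance + [{"step": "assign_population", "n_in": len(occ),
                                  "n_out": len(sub), "population": m.taxon}]
        out[m.taxon] = OccurrenceSet(m.taxon, sub, prov)
    unassigned = OccurrenceSet(
        occ.taxon, occ.records[assigned_to < 0].reset_index(drop=True),
        occ.provenance + [{"step": "assign_population_unassigned", "n_in": len(occ),
                           "n_out": int((assigned_to < 0).sum())}])
    return out, unassigned


def prepare(occ: OccurrenceSet, m: AccessibleArea, window: SeasonWindow | None = None,
            min_km: float = 20.0, drop_undated: bool = True) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Full cleaning chain: dedupe -> season filter -> M clip -> rarefy.

    Returns (cleaned set, outliers removed by the M clip).
    """
    occ = dedupe(occ)
    occ = season_filter(occ, window=window, drop_undated=drop_undated)
    occ, outliers = clip_to_m(occ, m)
    occ = rarefy(occ, min_km=min_km)
    return occ, outliers
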