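"""Trajectory containers and tabular I/O for AIS-style position reports.

The universal input to every detector is a :class:`Track`: a time-ordered
sequence of position reports (UTC timestamp, WGS84 latitude/longitude, speed
over ground in knots) for a single vessel, optionally carrying an activity
label ``"F"`` (fishing) or ``"NF"`` (non-fishing) assigned by an expert, a
simulator, or a detector.  Tracks are stored as pandas DataFrames internally;
:class:`TrackPoint` provides a per-report record view.

File format: delimited text (comma by default), UTF-8, header row required,
one row per position report.  Column names are configurable through a
``column_map``; the defaults follow common AIS export conventions
(``mmsi, timestamp, lat, lon, sog, label``).  Timestamps may be ISO-8601
strings or epoch seconds.  A GeoJSON point-feature writer is provided as a
secondary export for mapping tools.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABEL_FISHING = "F"
LABEL_NONFISHING = "NF"
VALID_LABELS = (LABEL_FISHING, LABEL_NONFISHING)

#: Default file-column names for each logical field.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "vessel_id": "mmsi",
    "t": "timestamp",
    "lat": "lat",
    "lon": "lon",
    "sog": "sog",
    "label": "label",
}

_REQUIRED_FIELDS = ("vessel_id", "t", "lat", "lon", "sog")


class ColumnMappingError(KeyError):
    """A required column could not be resolved in the input file."""


class EmptyInputError(ValueError):
    """The input file contained no valid position reports."""


@dataclass(frozen=True)
class TrackPoint:
    """A single position report."""

    vessel_id: str
    t: pd.Timestamp
    lat: float
    lon: float
    sog: float
    label: Optional[str] = None
    is_day: Optional[bool] = None
    shore_km: Optional[float] = None


class Track:
    """A single vessel's time-ordered sequence of position reports.

    Parameters
    ----------
    vessel_id : str
        Vessel identifier (e.g. MMSI).
    points : pandas.DataFrame
        Must contain columns ``t`` (UTC datetimes), ``lat``, ``lon``, ``sog``.
        Optional columns: ``label``, ``is_day``, ``shore_km``, ``phase``.
    """

    def __init__(self, vessel_id: str, points: pd.DataFrame):
        df = points.reset_index(drop=True)
        if "t" in df.columns and not isinstance(df["t"].dtype, pd.DatetimeTZDtype):
            df = df.assign(t=pd.to_datetime(df["t"], utc=True))
        self.vessel_id = str(vessel_id)
        self.points = df

    def __len__(self) -> int:
        return len(self.points)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Track(vessel_id={self.vessel_id!r}, n={len(self)})"

    def copy(self) -> "Track":
        return Track(self.vessel_id, self.points.copy())

    @property
    def times_hours(self) -> np.ndarray:
        """Report times as hours elapsed since the first report."""
        t = self.points["t"]
        return ((t - t.iloc[0]).dt.total_seconds() / 3600.0).to_numpy()

    def to_points(self) -> list[TrackPoint]:
        """Materialize per-report records (convenience view)."""
        out = []
        for row in self.points.itertuples(index=False):
            out.append(
                TrackPoint(
                    vessel_id=self.vessel_id,
                    t=row.t,
                    lat=float(row.lat),
                    lon=float(row.lon),
                    sog=float(row.sog),
                    label=getattr(row, "label", None),
                    is_day=getattr(row, "is_day", None),
                    shore_km=getattr(row, "shore_km", None),
                )
            )
        return out


@dataclass(frozen=True)
class Shoreline:
    """Coastal vertex set used for minimum-distance-to-shore computation.

    ``vertices`` is an (n, 2) array of (lat, lon) in degrees.  Distance to
    shore is vertex-based: accuracy is bounded by the vertex spacing of the
    source shoreline data.
    """

    vertices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) == 0:
            raise ValueError("shoreline must be a non-empty (n, 2) array of (lat, lon)")
        if np.any(np.abs(v[:, 0]) > 90) or np.any(np.abs(v[:, 1]) > 180):
            raise ValueError("shoreline vertex out of coordinate bounds")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)


def validate_track(track: Track) -> list[str]:
    """Check Track invariants; return human-readable violations (empty = valid).

    Checked: length >= 1, strictly increasing timestamps, latitude in
    [-90, 90], longitude in [-180, 180], speed over ground finite and >= 0.
    Never mutates the input.
    """
    violations: list[str] = []
    df = track.points
    if len(df) < 1:
        return ["track is empty"]
    t = df["t"].to_numpy()
    if len(df) > 1 and not np.all(t[1:] > t[:-1]):
        bad = int(np.argmin(t[1:] > t[:-1]))
        violations.append(f"timestamps not strictly increasing at row {bad + 1}")
    lat = df["lat"].to_numpy(dtype=float)
    lon = df["lon"].to_numpy(dtype=float)
    sog = df["sog"].to_numpy(dtype=float)
    for i in np.flatnonzero((np.abs(lat) > 90) | ~np.isfinite(lat)):
        violations.append(f"latitude out of bounds at row {i}: {lat[i]}")
    for i in np.flatnonzero((np.abs(lon) > 180) | ~np.isfinite(lon)):
        violations.append(f"longitude out of bounds at row {i}: {lon[i]}")
    for i in np.flatnonzero(~np.isfinite(sog) | (sog < 0)):
        violations.append(f"negative or non-finite speed at row {i}: {sog[i]}")
    return violations


def _resolve_columns(
    df: pd.DataFrame, column_map: Optional[Mapping[str, str]]
) -> dict[str, str]:
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    for field_name in _REQUIRED_FIELDS:
        if cmap[field_name] not in df.columns:
            raise ColumnMappingError(
                f"required column {cmap[field_name]!r} (field {field_name!r}) "
                f"not found; available: {list(df.columns)}"
            )
    return cmap


def _parse_times(raw: pd.Series) -> pd.Series:
    """Parse ISO-8601 strings or epoch seconds to UTC datetimes (NaT on failure)."""
    if pd.api.types.is_numeric_dtype(raw):
        return pd.to_datetime(raw, unit="s", utc=True, errors="coerce")
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        return pd.to_datetime(numeric, unit="s", utc=True, errors="coerce")
    return pd.to_datetime(raw, utc=True, errors="coerce", format="ISO8601")


def read_tracks(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: str = ",",
) -> list[Track]:
    """Read a delimited position-report table into one Track per vessel.

    Rows that fail to parse (bad timestamp, non-numeric coordinate/speed,
    out-of-bounds position) are rejected and logged with their row numbers.
    Duplicate (vessel, timestamp) rows keep the first occurrence.  Label
    values other than ``"F"``/``"NF"`` are treated as unlabeled with a
    warning.

    Raises
    ------
    ColumnMappingError
        If a required column cannot be resolved.
    EmptyInputError
        If no valid rows remain.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype={0: str})
    cmap = _resolve_columns(raw, column_map)

    df = pd.DataFrame(
        {
            "vessel_id": raw[cmap["vessel_id"]].astype(str),
            "t": _parse_times(raw[cmap["t"]]),
            "lat": pd.to_numeric(raw[cmap["lat"]], errors="coerce"),
            "lon": pd.to_numeric(raw[cmap["lon"]], errors="coerce"),
            "sog": pd.to_numeric(raw[cmap["sog"]], errors="coerce"),
        }
    )
    ok = (
        df["t"].notna()
        & df["lat"].between(-90, 90)
        & df["lon"].between(-180, 180)
        & df["sog"].ge(0)
        & np.isfinite(df["sog"].to_numpy(dtype=float, na_value=np.nan))
    )
    rejected = np.flatnonzero(~ok.to_numpy())
    if len(rejected):
        logger.warning(
            "rejected %d unparseable row(s): rows %s",
            len(rejected),
            rejected[:20].tolist(),
        )
    df = df.loc[ok]

    if cmap["label"] in raw.columns:
        lab = raw.loc[df.index, cmap["label"]].astype("string").str.strip()
        alien = lab.notna() & ~lab.isin(VALID_LABELS)
        if alien.any():
            logger.warning(
                "%d label value(s) outside {F, NF} treated as unlabeled", int(alien.sum())
            )
        df["label"] = lab.where(lab.isin(VALID_LABELS), pd.NA)

    if df.empty:
        raise EmptyInputError(f"no valid position reports in {path}")

    df = df.sort_values(["vessel_id", "t"], kind="stable")
    before = len(df)
    df = df.drop_duplicates(subset=["vessel_id", "t"], keep="first")
    if len(df) < before:
        logger.warning("dropped %d duplicate (vessel, timestamp) row(s)", before - len(df))

    tracks = [
        Track(vid, sub.drop(columns="vessel_id"))
        for vid, sub in df.groupby("vessel_id", sort=True)
    ]
    return tracks


def _export_frame(tracks: Iterable[Track], require_labels: bool) -> pd.DataFrame:
    frames = []
    for tr in tracks:
        df = tr.points.copy()
        if require_labels:
            if "label" not in df.columns or df["label"].isna().any():
                raise ValueError(
                    f"track {tr.vessel_id!r} has unlabeled points; "
                    "write_labels requires a label on every point"
                )
        df.insert(0, "vessel_id", tr.vessel_id)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["vessel_id", "t", "lat", "lon", "sog", "label"]
        )
    return pd.concat(frames, ignore_index=True)


def write_labels(
    tracks: Sequence[Track],
    path,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: str = ",",
) -> None:
    """Write labeled tracks to a delimited table, round-trip stable with
    :func:`read_tracks`.  Every point must carry a label."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = _export_frame(tracks, require_labels=True)
    out = pd.DataFrame(
        {
            cmap["vessel_id"]: df["vessel_id"] if len(df) else [],
            cmap["t"]: df["t"].dt.strftime("%Y-%m-%dT%H:%M:%SZ") if len(df) else [],
            cmap["lat"]: df["lat"] if len(df) else [],
            cmap["lon"]: df["lon"] if len(df) else [],
            cmap["sog"]: df["sog"] if len(df) else [],
            cmap["label"]: df["label"] if len(df) else [],
        }
    )
    out.to_csv(path, sep=delimiter, index=False)


def write_geojson(tracks: Sequence[Track], path) -> None:
    """Export labeled points as a GeoJSON FeatureCollection (one Point per report)."""
    features = []
    for tr in tracks:
        for row in tr.points.itertuples(index=False):
            props = {
                "vessel_id": tr.vessel_id,
                "t": row.t.strftime("%Y-%m-%dT%H:%M:%SZ"),
                "sog": float(row.sog),
            }
            label = getattr(row, "label", None)
            if label is not None and not (isinstance(label, float) and math.isnan(label)):
                props["label"] = str(label)
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [float(row.lon), float(row.lat)],
                    },
                    "properties": props,
                }
            )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _geojson_vertices(obj) -> list[tuple[float, float]]:
    """Extract (lat, lon) vertices from GeoJSON geometry/feature objects."""
    verts: list[tuple[float, float]] = []

    def from_geometry(geom):
        gtype = geom.get("type")
        coords = geom.get("coordinates", [])
        if gtype == "Point":
            verts.append((coords[1], coords[0]))
        elif gtype in ("LineString", "MultiPoint"):
            verts.extend((c[1], c[0]) for c in coords)
        elif gtype in ("MultiLineString", "Polygon"):
            for part in coords:
                verts.extend((c[1], c[0]) for c in part)
        elif gtype == "MultiPolygon":
            for poly in coords:
                for ring in poly:
                    verts.extend((c[1], c[0]) for c in ring)
        elif gtype == "GeometryCollection":
            for g in geom.get("geometries", []):
                from_geometry(g)

    if obj.get("type") == "FeatureCollection":
        for feat in obj.get("features", []):
            from_geometry(feat.get("geometry", {}))
    elif obj.get("type") == "Feature":
        from_geometry(obj.get("geometry", {}))
    else:
        from_geometry(obj)
    return verts


def load_shoreline(path) -> Shoreline:
    """Load a shoreline vertex set.

    Accepts (a) a two-column delimited text file with a header containing
    ``lat`` and ``lon`` columns, or (b) a GeoJSON file whose geometries'
    vertices are extracted (Point, LineString, MultiLineString, polygons).
    """
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.read(1)
    if head in ("{", "["):
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        verts = _geojson_vertices(obj)
        if not verts:
            raise EmptyInputError(f"no shoreline vertices found in {path}")
        return Shoreline(np.asarray(verts, dtype=float))
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "lat" not in cols or "lon" not in cols:
        raise ColumnMappingError("shoreline table needs 'lat' and 'lon' columns")
    return Shoreline(df[[cols["lat"], cols["lon"]]].to_numpy(dtype=float))
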