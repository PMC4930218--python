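"""Trajectory preprocessing: geodesy, day/night flagging, regularization.

Three ingredients every detector relies on:

* great-circle (haversine) distance on a sphere of mean radius 6371.0 km,
  and from it the minimum distance from a position to a shoreline vertex set
  (the 10 km coastal exclusion used to mask port/near-shore maneuvering);
* a binary day/night flag from the sign of the solar elevation angle,
  computed from the standard declination + equation-of-time + hour-angle
  construction (the truncated-Meeus series of the NOAA solar calculator);
* time regularization onto a fixed grid (7 h by default) with linear
  interpolation of positions between bracketing fixes, splitting the track
  wherever the gap between consecutive reports exceeds ``max_gap_hours`` —
  the form required by minimum-contrast segmentation, which assumes an
  evenly sampled series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .tracks import Shoreline, Track

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
KM_PER_NM = 1.852


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius 6371.0 km.

    Accepts scalars or broadcastable arrays of degrees.  Symmetric,
    non-negative, zero iff the endpoints coincide.

    Raises
    ------
    ValueError
        If any coordinate is outside [-90, 90] lat / [-180, 180] lon.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude out of [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180):
            raise ValueError("longitude out of [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def _unit_vectors(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    phi, lam = np.radians(lat), np.radians(lon)
    return np.column_stack(
        (np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi))
    )


def distance_to_shore(lat, lon, shoreline: Shoreline, method: str = "auto"):
    """Minimum haversine distance (km) from point(s) to shoreline vertices.

    ``method='exhaustive'`` scans every vertex; ``method='kdtree'`` finds the
    nearest vertex by chord distance on the unit sphere (monotone in central
    angle, hence the same argmin) and returns the identical haversine value.
    ``'auto'`` picks the KD-tree for more than 32 vertices.
    """
    if len(shoreline) == 0:
        raise ValueError("empty shoreline")
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    scalar = lat.size == 1 and np.isscalar(lat.flat[0])

    if method == "auto":
        method = "kdtree" if len(shoreline) > 32 else "exhaustive"
    sv = shoreline.vertices
    if method == "kdtree":
        tree = cKDTree(_unit_vectors(sv[:, 0], sv[:, 1]))
        _, idx = tree.query(_unit_vectors(lat, lon))
        d = haversine_km(lat, lon, sv[idx, 0], sv[idx, 1])
    elif method == "exhaustive":
        d = np.array(
            [np.min(haversine_km(la, lo, sv[:, 0], sv[:, 1])) for la, lo in zip(lat, lon)]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    d = np.atleast_1d(d)
    return float(d[0]) if scalar and d.size == 1 else d


# ---------------------------------------------------------------------------
# Solar position (NOAA solar-calculator formulas)
# ---------------------------------------------------------------------------

def _solar_geometry(t: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray]:
    """Solar declination (radians) and equation of time (minutes).

    The NOAA solar-calculator series (truncated Meeus): geometric mean
    longitude/anomaly plus the equation of center, apparent longitude with
    nutation, and the obliquity-based equation of time.  Sunrise/sunset
    timing is accurate to well under a minute at mid latitudes — ample for
    a binary day/night flag.
    """
    jd = t.to_julian_date().to_numpy() if hasattr(t, "to_julian_date") else np.asarray(t)
    T = (jd - 2451545.0) / 36525.0
    L0 = np.radians((280.46646 + 36000.76983 * T + 0.0003032 * T * T) % 360.0)
    M = np.radians(357.52911 + 35999.05029 * T - 0.0001537 * T * T)
    e = 0.016708634 - 0.000042037 * T - 0.0000001267 * T * T
    C = np.radians(
        (1.914602 - 0.004817 * T - 0.000014 * T * T) * np.sin(M)
        + (0.019993 - 0.000101 * T) * np.sin(2 * M)
        + 0.000289 * np.sin(3 * M)
    )
    omega = np.radians(125.04 - 1934.136 * T)
    lam = L0 + C - np.radians(0.00569 + 0.00478 * np.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))
    decl = np.arcsin(np.sin(eps) * np.sin(lam))
    y = np.tan(eps / 2.0) ** 2
    eqtime = 4.0 * np.degrees(
        y * np.sin(2 * L0)
        - 2.0 * e * np.sin(M)
        + 4.0 * e * y * np.sin(M) * np.cos(2 * L0)
        - 0.5 * y * y * np.sin(4 * L0)
        - 1.25 * e * e * np.sin(2 * M)
    )
    return decl, eqtime


def _as_utc_index(t) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(t), utc=True))
    return idx


def solar_elevation_deg(lat, lon, t):
    """Solar elevation angle in degrees at (lat, lon) and UTC instant(s) t."""
    idx = _as_utc_index(t)
    lat = np.broadcast_to(np.asarray(lat, dtype=float), idx.shape)
    lon = np.broadcast_to(np.asarray(lon, dtype=float), idx.shape)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude out of [-90, 90]")
    decl, eqtime = _solar_geometry(idx)
    frac_min = (
        idx.hour.to_numpy(dtype=float) * 60.0
        + idx.minute.to_numpy(dtype=float)
        + idx.second.to_numpy(dtype=float) / 60.0
    )
    true_solar_min = np.mod(frac_min + eqtime + 4.0 * lon, 1440.0)
    ha = np.radians(true_solar_min / 4.0 - 180.0)
    phi = np.radians(lat)
    cos_zen = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    elev = 90.0 - np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    return elev if elev.ndim and len(elev) > 1 else float(elev[0])


def is_day(lat, lon, t, refraction: bool = False):
    """True iff the sun is above the horizon at (lat, lon, t).

    Day is defined by the sign of the solar elevation (positive = day); with
    ``refraction=True`` the conventional -0.833 deg apparent-horizon
    correction (refraction plus solar radius) is applied instead.
    """
    threshold = -0.833 if refraction else 0.0
    elev = solar_elevation_deg(lat, lon, t)
    return elev > threshold


def annotate(track: Track, shoreline: Shoreline, offshore_km: float = 10.0) -> Track:
    """Attach ``is_day`` and ``shore_km`` to every point of a track.

    Points with ``shore_km`` below ``offshore_km`` are treated as
    out-of-domain by the downstream detectors (forced non-fishing).
    Idempotent: re-annotating replaces the same columns with the same values.
    """
    df = track.points.copy()
    lat = df["lat"].to_numpy(dtype=float)
    lon = df["lon"].to_numpy(dtype=float)
    df["is_day"] = np.atleast_1d(is_day(lat, lon, df["t"]))
    df["shore_km"] = np.atleast_1d(distance_to_shore(lat, lon, shoreline))
    out = Track(track.vessel_id, df)
    out.offshore_km = offshore_km
    return out


# ---------------------------------------------------------------------------
# Time regularization
# ---------------------------------------------------------------------------

@dataclass
class RegularTrack:
    """A track resampled to an exactly arithmetic time grid.

    ``points`` columns: ``t`` (UTC), ``lat``, ``lon``, ``sog`` (knots,
    defined as great-circle displacement per step).  Consecutive timestamps
    differ by exactly ``step_hours``.
    """

    vessel_id: str
    step_hours: float
    points: pd.DataFrame

    def __len__(self) -> int:
        return len(self.points)

    @property
    def origin(self) -> pd.Timestamp:
        return self.points["t"].iloc[0]

    @property
    def times_hours(self) -> np.ndarray:
        t = self.points["t"]
        return ((t - t.iloc[0]).dt.total_seconds() / 3600.0).to_numpy()


def regularize(
    track: Track, step_hours: float = 7.0, max_gap_hours: float = 24.0
) -> list[RegularTrack]:
    """Resample a track onto a fixed time grid, splitting at large gaps.

    The grid is anchored at the first report: t0, t0+step, t0+2*step, ...
    Within each gap-free span, grid positions are obtained by linear
    interpolation of lat/lon between the bracketing original fixes; no
    interpolation is performed across gaps longer than ``max_gap_hours``
    (the track is split instead).  Grid speed is the great-circle
    displacement between consecutive grid points divided by the step,
    expressed in knots (the first grid point inherits the second's speed).

    Spans yielding fewer than two grid points are dropped (logged).
    """
    if len(track) < 2:
        logger.warning("track %s too short to regularize", track.vessel_id)
        return []
    if step_hours <= 0:
        raise ValueError("step_hours must be positive")
    df = track.points
    th = track.times_hours
    lat = df["lat"].to_numpy(dtype=float)
    lon = df["lon"].to_numpy(dtype=float)
    t0 = df["t"].iloc[0]

    gap_after = np.flatnonzero(np.diff(th) > max_gap_hours)
    starts = np.concatenate(([0], gap_after + 1))
    ends = np.concatenate((gap_after, [len(th) - 1]))

    out: list[RegularTrack] = []
    eps = 1e-9
    for s, e in zip(starts, ends):
        if e <= s:
            continue
        k_min = int(np.ceil(th[s] / step_hours - eps))
        k_max = int(np.floor(th[e] / step_hours + eps))
        if k_max - k_min + 1 < 2:
            logger.info(
                "span [%g h, %g h] of track %s covers <2 grid points; dropped",
                th[s], th[e], track.vessel_id,
            )
            continue
        grid_h = np.arange(k_min, k_max + 1, dtype=float) * step_hours
        glat = np.interp(grid_h, th[s : e + 1], lat[s : e + 1])
        glon = np.interp(grid_h, th[s : e + 1], lon[s : e + 1])
        step_km = haversine_km(glat[:-1], glon[:-1], glat[1:], glon[1:])
        sog = np.empty(len(grid_h))
        sog[1:] = step_km / step_hours / KM_PER_NM
        sog[0] = sog[1]
        pts = pd.DataFrame(
            {
                "t": t0 + pd.to_timedelta(grid_h, unit="h"),
                "lat": glat,
                "lon": glon,
                "sog": sog,
            }
        )
        out.append(RegularTrack(track.vessel_id, float(step_hours), pts))
    return out
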