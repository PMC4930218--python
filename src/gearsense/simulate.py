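"""Synthetic labeled AIS-like track generation, one generator per gear type.

Real satellite-AIS fishing-vessel archives are proprietary, so every
detector here is exercised against synthetic tracks whose behavioral
envelopes follow the published kinematics of each gear:

* **trawler** — alternating steaming (~12 kn) and towing phases at slow,
  steady speeds uniform in 2.5-5.5 kn lasting 3-5 h; occasional slow drift
  and mid-speed searching provide non-fishing behavior that overlaps the
  towing speed band.
* **longliner** — steaming legs between grounds, then cycles of set (a long
  straight leg slightly below steaming speed, duration lognormal with median
  6.5 h), soak (slow drift looping near the end of the line), and haul
  (retracing the set leg at reduced speed).  Set, soak and haul are all
  fishing by the gear definition (deployment through retrieval of the last
  hooks).
* **purse seiner** — daylight-gated hauls at <= 2.5 kn lasting 1-3 h, with
  fast searching/transit (~14 kn) otherwise; seiners do not fish at night.

Positions are integrated by dead reckoning on a local tangent plane
re-projected at each behavioral leg, with additive GPS noise on the
reported coordinates.  Report intervals are irregular (exponential);
coverage dropouts are modeled separately by :func:`degrade`.  One seed
controls the phase schedule, kinematics, noise and gaps, so equal seeds
give bit-identical tracks.

The distribution parameters are surrogates chosen from the published speed
and duration envelopes, not fitted to any real AIS data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import solar_elevation_deg
from .tracks import LABEL_FISHING, LABEL_NONFISHING, Track

KM_PER_DEG_LAT = 111.32
NM_PER_DEG = 60.0

#: phases counted as fishing, by gear definition
FISHING_PHASES = {"trawl", "set", "soak", "haul"}


@dataclass(frozen=True)
class GearProfile:
    """Behavioral envelope of one gear type (all speeds in knots)."""

    gear: str
    steaming_speed: tuple[float, float] = (12.0, 1.5)  # mean, sd
    fishing_speed_range: tuple[float, float] = (2.5, 5.5)
    event_duration_hours: tuple[float, float] = (3.0, 5.0)
    report_interval_min: float = 10.0  # mean of exponential inter-report time
    min_interval_min: float = 2.0
    gap_prob: float = 0.0  # per-report probability of a coverage gap
    gap_duration_hours: tuple[float, float] = (1.0, 6.0)
    gps_noise_sd_km: float = 0.05
    day_only: bool = False
    start_lat: float = 45.0
    start_lon: float = -150.0

    def __post_init__(self) -> None:
        lo, hi = self.fishing_speed_range
        if not (0 <= lo <= hi):
            raise ValueError("fishing_speed_range must be ordered and non-negative")
        if hi > self.steaming_speed[0]:
            raise ValueError("fishing speeds must lie below the mean steaming speed")
        if self.report_interval_min <= 0 or self.gps_noise_sd_km < 0:
            raise ValueError("profile parameters must be positive")


def trawler_profile(**overrides) -> GearProfile:
    return replace(GearProfile(gear="trawler"), **overrides)


def longliner_profile(**overrides) -> GearProfile:
    base = GearProfile(
        gear="longliner",
        steaming_speed=(11.5, 1.0),
        fishing_speed_range=(0.3, 9.5),  # soak drift up to set speed
        event_duration_hours=(6.5, 0.3),  # lognormal: median, sigma
        report_interval_min=12.0,
        start_lat=-10.0,
        start_lon=-120.0,
    )
    return replace(base, **overrides)


def seiner_profile(**overrides) -> GearProfile:
    base = GearProfile(
        gear="seiner",
        steaming_speed=(14.0, 1.2),
        fishing_speed_range=(0.2, 2.4),
        event_duration_hours=(1.0, 3.0),
        report_interval_min=8.0,
        day_only=True,
        start_lat=8.0,
        start_lon=-140.0,
    )
    return replace(base, **overrides)


class _TrackBuilder:
    """Dead-reckoning integrator accumulating reports phase by phase."""

    def __init__(self, rng: np.random.Generator, profile: GearProfile):
        self.rng = rng
        self.p = profile
        self.t = 0.0  # hours since origin
        self.lat = profile.start_lat
        self.lon = profile.start_lon
        self.rows: list[tuple[float, float, float, float, str, str]] = []

    # -- helpers -----------------------------------------------------------

    def _intervals(self, duration_h: float) -> np.ndarray:
        """Irregular report intervals (hours) summing to >= duration."""
        mean_h = self.p.report_interval_min / 60.0
        min_h = self.p.min_interval_min / 60.0
        n_guess = max(4, int(duration_h / mean_h * 1.6) + 4)
        dts = min_h + self.rng.exponential(max(mean_h - min_h, 1e-3), size=n_guess)
        while dts.sum() < duration_h:
            dts = np.concatenate(
                [dts, min_h + self.rng.exponential(max(mean_h - min_h, 1e-3), size=n_guess)]
            )
        keep = np.searchsorted(np.cumsum(dts), duration_h) + 1
        dts = dts[:keep]
        # trim the last interval so the phase lasts exactly duration_h
        overshoot = dts.sum() - duration_h
        dts[-1] = max(dts[-1] - overshoot, min_h / 2.0)
        return dts

    def _emit(self, dts, dlat, dlon, sogs, label, phase):
        """Append reports; (dlat, dlon) are per-report displacements (deg)."""
        lat = self.lat + np.cumsum(dlat)
        lon = self.lon + np.cumsum(dlon)
        times = self.t + np.cumsum(dts)
        noise_deg = self.p.gps_noise_sd_km / KM_PER_DEG_LAT
        rlat = lat + self.rng.normal(0.0, noise_deg, size=len(lat))
        rlon = lon + self.rng.normal(0.0, noise_deg, size=len(lon)) / np.cos(
            np.radians(np.clip(lat, -80, 80))
        )
        rlat = np.clip(rlat, -89.0, 89.0)
        rlon = ((rlon + 180.0) % 360.0) - 180.0
        for t_i, la, lo, s in zip(times, rlat, rlon, sogs):
            self.rows.append((t_i, la, lo, max(float(s), 0.0), label, phase))
        self.t = float(times[-1])
        self.lat = float(lat[-1])
        self.lon = float(lon[-1])

    def heading_choice(self, max_offset_deg: float = 8.0) -> float:
        """A fresh heading: uniform near the home ground, homeward when far.

        Vessels operate within a basin; beyond ``max_offset_deg`` of the
        profile's start position new legs steer back toward it, which keeps
        long simulations regional and away from the antimeridian.
        """
        dlat = self.p.start_lat - self.lat
        dlon = self.p.start_lon - self.lon
        if np.hypot(dlat, dlon) <= max_offset_deg:
            return float(self.rng.uniform(0, 360))
        coslat = np.cos(np.radians(np.clip(self.lat, -80, 80)))
        bearing = np.degrees(np.arctan2(dlon * coslat, dlat))
        return float(bearing + self.rng.uniform(-30, 30))

    def leg(
        self,
        duration_h: float,
        speed_fn,
        heading_deg: float,
        heading_drift_sd: float,
        label: str,
        phase: str,
    ) -> None:
        """A directed leg: per-report speeds from ``speed_fn(n)``, heading
        random-walking around ``heading_deg``."""
        dts = self._intervals(duration_h)
        n = len(dts)
        sogs = np.maximum(np.asarray(speed_fn(n), dtype=float), 0.0)
        headings = np.radians(
            heading_deg + np.cumsum(self.rng.normal(0.0, heading_drift_sd, size=n))
        )
        dist_nm = sogs * dts
        coslat = np.cos(np.radians(np.clip(self.lat, -80, 80)))
        dlat = dist_nm * np.cos(headings) / NM_PER_DEG
        dlon = dist_nm * np.sin(headings) / (NM_PER_DEG * coslat)
        self._emit(dts, dlat, dlon, sogs, label, phase)

    def drift_loop(self, duration_h: float, max_speed_kn: float, label: str, phase: str) -> None:
        """A slow random-walk drift bridged back to its starting position.

        Per-report drift speeds stay below ~0.85 * ``max_speed_kn``; the
        bridge correction adds only |total drift| / duration, so reported
        speeds remain safely under ``max_speed_kn``.
        """
        dts = self._intervals(duration_h)
        n = len(dts)
        u = self.rng.uniform(0.05, 0.8, size=n) * max_speed_kn
        ang = self.rng.uniform(0.0, 2.0 * np.pi, size=n)
        step_deg = u * dts / NM_PER_DEG
        wlat = np.cumsum(step_deg * np.cos(ang))
        wlon_eq = np.cumsum(step_deg * np.sin(ang))  # east displacement, deg-equivalent
        frac = np.cumsum(dts) / dts.sum()
        plat = wlat - frac * wlat[-1]
        plon_eq = wlon_eq - frac * wlon_eq[-1]
        dlat = np.diff(np.concatenate(([0.0], plat)))
        dlon_eq = np.diff(np.concatenate(([0.0], plon_eq)))
        coslat = np.cos(np.radians(np.clip(self.lat, -80, 80)))
        # report the speed implied by the actual drift displacement
        sogs = np.hypot(dlat, dlon_eq) * NM_PER_DEG / dts
        self._emit(dts, dlat, dlon_eq / coslat, sogs, label, phase)

    def transit_to(self, target_lat, target_lon, speed_fn, label, phase) -> None:
        """A straight leg ending exactly at (target_lat, target_lon)."""
        coslat = np.cos(np.radians(np.clip(self.lat, -80, 80)))
        dx = (target_lon - self.lon) * coslat
        dy = target_lat - self.lat
        total_nm = np.hypot(dx, dy) * NM_PER_DEG
        probe = max(float(np.mean(speed_fn(8))), 0.5)
        duration_h = max(total_nm / probe, 1e-2)
        dts = self._intervals(duration_h)
        n = len(dts)
        sogs = np.maximum(np.asarray(speed_fn(n), dtype=float), 0.2)
        covered = np.cumsum(sogs * dts)
        frac = covered / covered[-1]
        plat = frac * dy
        plon = frac * (target_lon - self.lon)
        dlat = np.diff(np.concatenate(([0.0], plat)))
        dlon = np.diff(np.concatenate(([0.0], plon)))
        self._emit(dts, dlat, dlon, sogs, label, phase)

    def to_track(self, vessel_id: str, t0: pd.Timestamp) -> Track:
        df = pd.DataFrame(
            self.rows, columns=["th", "lat", "lon", "sog", "label", "phase"]
        )
        df["t"] = t0 + pd.to_timedelta(np.round(df["th"] * 3600.0), unit="s")
        df = df.drop_duplicates(subset="t", keep="first")
        return Track(vessel_id, df[["t", "lat", "lon", "sog", "label", "phase"]])


def _truncnorm(rng, mean, sd, size, low=0.0):
    v = rng.normal(mean, sd, size=size)
    return np.maximum(v, low)


def simulate_trawler(
    n_hours: float,
    seed: int,
    profile: Optional[GearProfile] = None,
    t0: pd.Timestamp | str = "2013-07-01T00:00:00Z",
) -> Track:
    """Synthetic trawler track: steaming/searching/drifting vs towing.

    Tow phases: per-report speed uniform in ``fishing_speed_range``
    (2.5-5.5 kn), duration uniform in ``event_duration_hours`` (3-5 h),
    gentle heading drift.  Non-fishing mixes fast steaming (Normal around
    12 kn), mid-speed searching that overlaps the upper tow band, and slow
    drift.  Deterministic per seed.
    """
    p = profile or trawler_profile()
    rng = np.random.default_rng(seed)
    b = _TrackBuilder(rng, p)
    heading = float(rng.uniform(0, 360))
    while b.t < n_hours:
        kind = rng.choice(["steam", "search", "drift"], p=[0.6, 0.25, 0.15])
        if kind == "steam":
            heading = b.heading_choice()
            b.leg(
                float(rng.uniform(4, 12)),
                lambda n: _truncnorm(rng, p.steaming_speed[0], p.steaming_speed[1], n),
                heading, 2.0, LABEL_NONFISHING, "steam",
            )
        elif kind == "search":
            b.leg(
                float(rng.uniform(2, 5)),
                lambda n: rng.uniform(4.5, 8.0, size=n),
                heading + float(rng.uniform(-60, 60)), 10.0, LABEL_NONFISHING, "search",
            )
        else:
            b.drift_loop(float(rng.uniform(1, 3)), 1.5, LABEL_NONFISHING, "drift")
        if b.t >= n_hours:
            break
        lo, hi = p.fishing_speed_range
        b.leg(
            float(rng.uniform(*p.event_duration_hours)),
            lambda n: rng.uniform(lo, hi, size=n),
            heading + float(rng.uniform(-90, 90)), 8.0, LABEL_FISHING, "trawl",
        )
    return b.to_track(f"SIM-TRAWLER-{seed}", pd.Timestamp(t0))


def simulate_longliner(
    n_hours: float,
    seed: int,
    profile: Optional[GearProfile] = None,
    t0: pd.Timestamp | str = "2013-01-05T00:00:00Z",
) -> Track:
    """Synthetic longliner track: steam -> (set, soak, haul) cycles.

    Sets are straight legs slightly below steaming speed with lognormal
    duration (median ``event_duration_hours[0]`` = 6.5 h, log-sd the second
    entry); the soak is a slow drift loop at the line's end; the haul
    retraces the set leg back to its start at reduced speed, so haul
    endpoints coincide with set endpoints up to GPS noise.  Set, soak and
    haul points are labeled F.  Deterministic per seed.
    """
    p = profile or longliner_profile()
    rng = np.random.default_rng(seed)
    b = _TrackBuilder(rng, p)
    median_set, log_sd = p.event_duration_hours
    while b.t < n_hours:
        heading = b.heading_choice()
        b.leg(
            float(rng.uniform(24, 48)),
            lambda n: _truncnorm(rng, p.steaming_speed[0], p.steaming_speed[1], n),
            heading, 1.5, LABEL_NONFISHING, "steam",
        )
        n_sets = int(rng.integers(4, 10))
        for _ in range(n_sets):
            if b.t >= n_hours:
                break
            set_start = (b.lat, b.lon)
            set_heading = float(rng.uniform(0, 360))
            set_speed = float(_truncnorm(rng, 9.5, 0.5, 1)[0])
            set_dur = float(median_set * np.exp(rng.normal(0.0, log_sd)))
            b.leg(
                set_dur,
                lambda n: _truncnorm(rng, set_speed, 0.2, n),
                set_heading, 0.8, LABEL_FISHING, "set",
            )
            b.drift_loop(float(rng.uniform(2, 6)), 2.0, LABEL_FISHING, "soak")
            haul_speed = float(_truncnorm(rng, 4.5, 0.4, 1, low=2.0)[0])
            b.transit_to(
                set_start[0], set_start[1],
                lambda n: _truncnorm(rng, haul_speed, 0.2, n),
                LABEL_FISHING, "haul",
            )
    return b.to_track(f"SIM-LONGLINER-{seed}", pd.Timestamp(t0))


def _daylight_window(
    lat: float, lon: float, t0: pd.Timestamp, noon_h: float
) -> tuple[float, float]:
    """(sunrise, sunset) in hours after ``t0`` for the daylight block around
    the local solar noon at ``noon_h`` (hours after t0), by scanning the
    solar elevation on a 2-minute grid.  NaN during polar night."""
    offsets_min = np.arange(-10 * 60, 10 * 60, 2)
    times = t0 + pd.to_timedelta(noon_h * 60.0 + offsets_min, unit="m")
    elev = np.atleast_1d(solar_elevation_deg(lat, lon, times))
    up = np.flatnonzero(elev > 0)
    if up.size == 0:
        return (np.nan, np.nan)
    return (
        noon_h + offsets_min[up[0]] / 60.0,
        noon_h + offsets_min[up[-1]] / 60.0,
    )


def simulate_seiner(
    n_days: int,
    seed: int,
    profile: Optional[GearProfile] = None,
    t0: pd.Timestamp | str = "2013-03-01T00:00:00Z",
) -> Track:
    """Synthetic purse-seiner track: daylight hauls amid fast search/transit.

    Per day, 0-2 hauls (slow drift at <= 2.5 kn, 1-3 h) are scheduled
    strictly inside the daylight window at the vessel's position; all other
    time is searching or transiting near 14 kn, day and night, which puts a
    second non-fishing speed mode around 15 kn.  Haul points are labeled F.
    Deterministic per seed.
    """
    p = profile or seiner_profile()
    rng = np.random.default_rng(seed)
    b = _TrackBuilder(rng, p)
    t0 = pd.Timestamp(t0)
    heading = float(rng.uniform(0, 360))

    def steam_until(target_h: float, phase: str = "search") -> None:
        nonlocal heading
        while b.t < target_h - 1e-6:
            heading = 0.75 * heading + 0.25 * b.heading_choice(max_offset_deg=5.0) \
                + float(rng.uniform(-25, 25))
            b.leg(
                min(float(rng.uniform(1.5, 4.0)), target_h - b.t),
                lambda n: _truncnorm(rng, p.steaming_speed[0], p.steaming_speed[1], n),
                heading, 4.0, LABEL_NONFISHING, phase,
            )

    for day in range(int(n_days)):
        # daylight block around this calendar day's local solar noon
        noon_h = 12.0 - b.lon / 15.0 + 24.0 * day
        sunrise, sunset = _daylight_window(b.lat, b.lon, t0, noon_h)
        n_hauls = int(rng.choice([0, 1, 2], p=[0.2, 0.6, 0.2]))
        if not np.isfinite(sunrise):
            n_hauls = 0
        for _ in range(n_hauls):
            dur = float(rng.uniform(*p.event_duration_hours))
            lo_start = max(b.t + 0.2, sunrise + 0.5)
            hi_start = sunset - dur - 0.5
            if lo_start >= hi_start:
                break
            start = float(rng.uniform(lo_start, hi_start))
            steam_until(start)
            b.drift_loop(dur, 2.4, LABEL_FISHING, "haul")
        steam_until(max(24.0 * (day + 1), b.t + 0.1))
    return b.to_track(f"SIM-SEINER-{seed}", t0)


def degrade(
    track: Track,
    gap_prob: float = 0.01,
    gap_duration_hours: tuple[float, float] = (1.0, 6.0),
    seed: int = 0,
) -> Track:
    """Drop runs of reports to emulate satellite coverage gaps.

    At each surviving report a gap opens with probability ``gap_prob``; its
    duration is uniform in ``gap_duration_hours`` and every report inside is
    dropped.  Order is preserved and ground-truth labels are retained on
    survivors.  ``gap_prob=0`` is the identity.  Deterministic per seed.
    """
    if gap_prob == 0:
        return track.copy()
    rng = np.random.default_rng(seed)
    th = track.times_hours
    keep = np.ones(len(th), dtype=bool)
    gap_end = -np.inf
    for i in range(len(th)):
        if th[i] < gap_end:
            keep[i] = False
            continue
        if rng.random() < gap_prob:
            gap_end = th[i] + rng.uniform(*gap_duration_hours)
            # the triggering report survives; the gap starts just after it
    return Track(track.vessel_id, track.points.loc[keep])
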