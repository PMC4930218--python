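"""Longliner fishing detection by trajectory segmentation and data mining.

Longliner speed distributions for fishing and non-fishing overlap almost
completely (the vessel sets the line near steaming speed and hauls it back
along the same leg), so a speed HMM does not work.  Instead the pipeline
borrows the movement-ecology toolbox used for area-restricted search in
animal predators:

1. regularize the track to a fixed step (7 h by default, roughly the time a
   longliner spends on a set) and take the per-step great-circle
   displacement as the segmented signal;
2. partition the series into K contiguous segments with Lavielle's
   minimum-contrast estimator (exact least-squares change-point dynamic
   program);
3. classify each segment as straight (mean turning cosine above +0.8 or
   below -0.8) -> non-fishing transit, or curved -> fishing candidate;
4. within curved segments, compute first-passage times through circles of
   30 radii spanning 0.1-1 coordinate degrees; segments whose maximum
   variance of log(FPT) over radii is <= 0.1 move like straight lines and
   are relabeled non-fishing;
5. estimate a kernel utilization distribution over the surviving candidate
   positions and relabel points outside the 95% isopleth (density below the
   5th percentile of candidate densities) as non-fishing.

Every stage after 3 only ever flips F -> NF: the pipeline is monotone,
trimming fishing candidates and never adding them.  Final grid labels are
mapped back to the original irregular reports by nearest-in-time assignment
within half a step; anything within 10 km of shore is forced NF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator

from .preprocess import RegularTrack, haversine_km, regularize
from .tracks import LABEL_FISHING, LABEL_NONFISHING, Shoreline, Track

logger = logging.getLogger(__name__)

DEFAULT_RADII = np.linspace(0.1, 1.0, 30)


# ---------------------------------------------------------------------------
# Lavielle minimum-contrast segmentation
# ---------------------------------------------------------------------------

@dataclass
class Segmentation:
    """A contiguous partition of a regular series into K segments.

    ``breakpoints`` holds the K-1 interior start indices (strictly
    increasing); segment k covers ``series[bounds[k]:bounds[k+1]]`` with
    ``bounds = [0, *breakpoints, n]``.  ``contrast`` is the total
    least-squares cost around segment means.
    """

    series: np.ndarray = field(repr=False)
    breakpoints: np.ndarray
    K: int
    Lmin: int
    contrast: float

    @property
    def bounds(self) -> np.ndarray:
        return np.concatenate(([0], self.breakpoints, [len(self.series)]))

    def segments(self) -> list[tuple[int, int]]:
        b = self.bounds
        return [(int(b[i]), int(b[i + 1])) for i in range(self.K)]


def _segment_costs(series: np.ndarray):
    """Closure c(i, j) = least-squares cost of series[i:j] via prefix sums."""
    x = np.asarray(series, dtype=float)
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def cost(i, j):
        n = j - i
        return (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / n

    return cost


def lavielle_segment(series, K: int, Lmin: int = 2) -> Segmentation:
    """Exact minimum-contrast segmentation into K segments.

    Minimizes the total within-segment least-squares contrast
    sum_k sum_{i in seg k} (x_i - mean(seg k))^2 over all contiguous
    partitions with segment length >= ``Lmin``, by dynamic programming.
    Deterministic; ties resolve to the lexicographically earliest breakpoint
    vector.

    Raises
    ------
    ValueError
        If K * Lmin exceeds the series length (infeasible).
    """
    x = np.asarray(series, dtype=float).ravel()
    n = len(x)
    if K < 1:
        raise ValueError("K must be >= 1")
    if Lmin < 1:
        raise ValueError("Lmin must be >= 1")
    if K * Lmin > n:
        raise ValueError(f"infeasible segmentation: K*Lmin = {K * Lmin} > n = {n}")
    cost = _segment_costs(x)

    # S[k][i]: minimal contrast of splitting x[i:n] into k segments.
    # Choosing the smallest feasible j at every state yields the
    # lexicographically earliest optimal breakpoint vector on reconstruction.
    NEG = np.inf
    S = np.full((K + 1, n + 1), NEG)
    arg = np.zeros((K + 1, n + 1), dtype=int)
    for i in range(n - Lmin, -1, -1):
        S[1][i] = cost(i, n)
    for k in range(2, K + 1):
        # x[i:n] into k segments: first segment ends at j
        for i in range(0, n - k * Lmin + 1):
            best, best_j = NEG, -1
            for j in range(i + Lmin, n - (k - 1) * Lmin + 1):
                v = cost(i, j) + S[k - 1][j]
                if v < best:
                    best, best_j = v, j
            S[k][i] = best
            arg[k][i] = best_j

    bps = []
    i = 0
    for k in range(K, 1, -1):
        j = int(arg[k][i])
        bps.append(j)
        i = j
    return Segmentation(
        series=x,
        breakpoints=np.asarray(bps, dtype=int),
        K=K,
        Lmin=Lmin,
        contrast=float(S[K][0]),
    )


# ---------------------------------------------------------------------------
# Straightness
# ---------------------------------------------------------------------------

def _local_xy(lat: np.ndarray, lon: np.ndarray, ref_lat: np.ndarray):
    """Planar displacement components about a reference latitude (degrees)."""
    return lon * np.cos(np.radians(ref_lat)), lat


def turning_cosines(points) -> np.ndarray:
    """Cosine of the turning angle at each interior point of a position list.

    ``points``: (n, 2) array of (lat, lon) degrees, or a DataFrame with
    ``lat``/``lon`` columns.  For each interior point, the cosine between the
    incoming and outgoing displacement vectors is computed on a local planar
    projection about that point.  A zero-length displacement contributes
    cosine 1 (no turn).  Fewer than three points yield an empty result.
    """
    if isinstance(points, pd.DataFrame):
        lat = points["lat"].to_numpy(dtype=float)
        lon = points["lon"].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        lat, lon = arr[:, 0], arr[:, 1]
    n = len(lat)
    if n < 3:
        return np.empty(0)
    ref = lat[1:-1]
    x_in, y_in = _local_xy(lat[1:-1] - lat[:-2], lon[1:-1] - lon[:-2], ref)
    x_out, y_out = _local_xy(lat[2:] - lat[1:-1], lon[2:] - lon[1:-1], ref)
    dot = x_in * x_out + y_in * y_out
    norm = np.hypot(x_in, y_in) * np.hypot(x_out, y_out)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(norm > 0, dot / np.where(norm == 0, 1, norm), 1.0)
    return np.clip(cos, -1.0, 1.0)


def classify_straight(
    segment_points, cos_threshold: float = 0.8, mode: str = "mean"
) -> bool:
    """Is a segment a straight-line movement?

    ``mode='mean'`` (default, the quantified rule): straight iff the mean
    turning cosine exceeds +threshold or falls below -threshold — forward
    transit and exact back-and-forth both count as straight.
    ``mode='majority'``: straight iff more than half the interior points have
    |cosine| > threshold.
    """
    cos = turning_cosines(segment_points)
    if cos.size == 0:
        raise ValueError("classify_straight needs at least 3 points")
    if mode == "mean":
        m = float(np.mean(cos))
        return m > cos_threshold or m < -cos_threshold
    if mode == "majority":
        return float(np.mean(np.abs(cos) > cos_threshold)) > 0.5
    raise ValueError(f"unknown straightness mode {mode!r}")


# ---------------------------------------------------------------------------
# First-passage time
# ---------------------------------------------------------------------------

def _pairwise_distance(lat, lon, i, metric):
    if metric == "degrees":
        return np.hypot(lon - lon[i], lat - lat[i])
    if metric == "km":
        return np.asarray(haversine_km(lat[i], lon[i], lat, lon))
    raise ValueError(f"unknown FPT metric {metric!r}")


def first_passage_times(
    lat, lon, times_hours, r: float, metric: str = "degrees"
) -> np.ndarray:
    """First-passage time (hours) through a circle of radius ``r`` per point.

    For point i, FPT is the time between the first backward and the first
    forward crossing of distance ``r`` from point i, with crossing instants
    linearly interpolated between the straddling fixes.  NaN where the path
    never exits the circle within the segment in either direction.

    ``metric='degrees'`` measures distance as raw Euclidean distance in
    coordinate degrees (the convention of the movement-ecology tools this
    mirrors); ``metric='km'`` uses great-circle distance.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    t = np.asarray(times_hours, dtype=float)
    if r <= 0:
        raise ValueError("radius must be positive")
    n = len(lat)
    out = np.full(n, np.nan)
    for i in range(n):
        d = _pairwise_distance(lat, lon, i, metric)
        # forward crossing
        fwd = np.nan
        outside = np.flatnonzero(d[i:] >= r)
        if outside.size:
            j = i + int(outside[0])
            if j == i:
                fwd = t[i]
            else:
                frac = (r - d[j - 1]) / (d[j] - d[j - 1])
                fwd = t[j - 1] + frac * (t[j] - t[j - 1])
        # backward crossing
        bwd = np.nan
        outside = np.flatnonzero(d[: i + 1][::-1] >= r)
        if outside.size:
            j = i - int(outside[0])
            if j == i:
                bwd = t[i]
            else:
                frac = (r - d[j + 1]) / (d[j] - d[j + 1])
                bwd = t[j + 1] - frac * (t[j + 1] - t[j])
        out[i] = fwd - bwd
    return out


class FPTFilterResult(NamedTuple):
    keep_fishing: bool
    radii: np.ndarray
    log_fpt_variance: np.ndarray  # NaN where fewer than 2 defined FPTs
    n_defined: np.ndarray


def fpt_variance_filter(
    lat,
    lon,
    times_hours,
    radii: Optional[np.ndarray] = None,
    var_threshold: float = 0.1,
    min_defined: int = 5,
    metric: str = "degrees",
) -> FPTFilterResult:
    """Decide whether a curved segment shows area-restricted movement.

    Computes S(r) = Var over points of log FPT(r) at each radius; the
    segment keeps its fishing label iff max_r S(r) exceeds
    ``var_threshold`` (0.1): near-zero variance at every scale means the
    vessel moves like a straight line and the segment is relabeled NF.
    If no radius has at least ``min_defined`` defined FPTs the decision is
    conservative (non-fishing) and logged.
    """
    if radii is None:
        radii = DEFAULT_RADII
    radii = np.asarray(radii, dtype=float)
    variances = np.full(len(radii), np.nan)
    n_def = np.zeros(len(radii), dtype=int)
    for k, r in enumerate(radii):
        fpt = first_passage_times(lat, lon, times_hours, r, metric=metric)
        good = fpt[np.isfinite(fpt) & (fpt > 0)]
        n_def[k] = len(good)
        if len(good) >= 2:
            variances[k] = float(np.var(np.log(good), ddof=1))
    if int(n_def.max(initial=0)) < min_defined:
        logger.warning(
            "FPT filter: fewer than %d defined first-passage times at every "
            "radius; segment conservatively labeled non-fishing",
            min_defined,
        )
        return FPTFilterResult(False, radii, variances, n_def)
    max_var = np.nanmax(variances) if np.any(np.isfinite(variances)) else 0.0
    return FPTFilterResult(bool(max_var > var_threshold), radii, variances, n_def)


# ---------------------------------------------------------------------------
# Utilization-distribution correction
# ---------------------------------------------------------------------------

def ud_correct(
    lat,
    lon,
    isopleth: float = 0.95,
    bw_method=None,
    min_points: int = 10,
) -> np.ndarray:
    """Keep-mask for candidate fishing points under a kernel UD.

    Fits a bivariate normal-kernel density (reference-rule bandwidth by
    default) on the candidate (lon, lat) cloud and relabels points whose
    density falls below the (1 - isopleth) quantile of candidate densities —
    i.e. points outside the smallest region holding ``isopleth`` of the
    density mass, operationally.  Returns a boolean array (True = keep F).

    Fewer than ``min_points`` candidates, or a degenerate point cloud
    (singular covariance), is a no-op: everything kept, warning logged.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    keep = np.ones(len(lat), dtype=bool)
    if not 0.0 < isopleth <= 1.0:
        raise ValueError("isopleth must be in (0, 1]")
    if len(lat) < min_points:
        logger.warning("UD correction skipped: %d < %d candidate points", len(lat), min_points)
        return keep
    try:
        kde = gaussian_kde(np.vstack((lon, lat)), bw_method=bw_method)
        dens = kde(np.vstack((lon, lat)))
    except np.linalg.LinAlgError:
        logger.warning("UD correction skipped: degenerate candidate geometry")
        return keep
    thr = np.quantile(dens, 1.0 - isopleth)
    return dens >= thr


# ---------------------------------------------------------------------------
# End-to-end detector
# ---------------------------------------------------------------------------

def _auto_K(n_steps: int, K_ref: int, n_ref_steps: int, Lmin: int) -> int:
    k = max(2, int(round(K_ref * n_steps / n_ref_steps)))
    return max(1, min(k, n_steps // Lmin))


@dataclass
class SegmentDecision:
    """Per-segment diagnostic row emitted by :func:`detect_longline`."""

    burst: int
    start: int
    end: int
    mean_cos: float
    straight: bool
    fpt_max_var: float
    decision: str  # "NF-straight", "NF-fpt", "F-candidate"


def detect_longline(
    track: Track,
    shoreline: Optional[Shoreline] = None,
    *,
    step_hours: float = 7.0,
    max_gap_hours: float = 24.0,
    K="auto",
    K_ref: int = 70,
    n_ref_steps: int = 1960,
    Lmin: int = 2,
    cos_threshold: float = 0.8,
    straight_mode: str = "mean",
    radii: Optional[np.ndarray] = None,
    fpt_var_threshold: float = 0.1,
    fpt_metric: str = "degrees",
    ud_isopleth: float = 0.95,
    offshore_km: float = 10.0,
    signal: str = "displacement",
    return_diagnostics: bool = False,
):
    """Per-point F/NF labels for a longliner track (aligned to the input).

    The track should carry ``shore_km`` (see :func:`gearsense.preprocess.
    annotate`); alternatively pass ``shoreline`` and distances are computed
    here.  With neither, the coastal mask is skipped with a warning.

    ``K='auto'`` scales the segment count with the regularized track length,
    K = round(K_ref * n_steps / n_ref_steps) with a floor of 2, so that the
    per-segment step budget matches the scale the default K_ref=70 was tuned
    at; pass an integer to override.  ``signal`` selects the series handed to
    the change-point estimator: per-step great-circle displacement in km
    (default) or the grid ``speed``.

    Returns the label array, plus a per-segment diagnostics DataFrame when
    ``return_diagnostics`` is true.
    """
    n_points = len(track)
    labels = np.full(n_points, LABEL_NONFISHING, dtype=object)
    diagnostics: list[SegmentDecision] = []

    bursts = regularize(track, step_hours=step_hours, max_gap_hours=max_gap_hours)
    if not bursts:
        logger.warning(
            "track %s too short to regularize; all points labeled NF", track.vessel_id
        )
        return _finish(track, labels, shoreline, offshore_km, diagnostics, return_diagnostics)

    grid_t: list[np.ndarray] = []
    grid_lab: list[np.ndarray] = []
    cand_lat: list[np.ndarray] = []
    cand_lon: list[np.ndarray] = []
    cand_ref: list[tuple[int, np.ndarray]] = []  # (burst idx, grid indices)

    for b_idx, burst in enumerate(bursts):
        glat = burst.points["lat"].to_numpy(dtype=float)
        glon = burst.points["lon"].to_numpy(dtype=float)
        gth = burst.times_hours
        n_grid = len(burst)
        blab = np.full(n_grid, LABEL_NONFISHING, dtype=object)

        if signal == "displacement":
            series = np.asarray(haversine_km(glat[:-1], glon[:-1], glat[1:], glon[1:]))
        elif signal == "speed":
            series = burst.points["sog"].to_numpy(dtype=float)[1:]
        else:
            raise ValueError(f"unknown signal {signal!r}")

        m = len(series)
        if m < Lmin:
            grid_t.append(gth)
            grid_lab.append(blab)
            continue
        k_here = _auto_K(m, K_ref, n_ref_steps, Lmin) if K == "auto" else min(int(K), m // Lmin)
        k_here = max(1, k_here)
        seg = lavielle_segment(series, k_here, Lmin=Lmin)

        for s, e in seg.segments():
            # series index i spans grid points i..i+1; segment [s, e) covers
            # grid points s..e inclusive
            pts_sl = slice(s, e + 1)
            seg_lat, seg_lon, seg_t = glat[pts_sl], glon[pts_sl], gth[pts_sl]
            if len(seg_lat) < 3:
                diagnostics.append(
                    SegmentDecision(b_idx, s, e, np.nan, True, np.nan, "NF-straight")
                )
                continue
            cos = turning_cosines(np.column_stack((seg_lat, seg_lon)))
            mean_cos = float(np.mean(cos))
            straight = classify_straight(
                np.column_stack((seg_lat, seg_lon)),
                cos_threshold=cos_threshold,
                mode=straight_mode,
            )
            if straight:
                diagnostics.append(
                    SegmentDecision(b_idx, s, e, mean_cos, True, np.nan, "NF-straight")
                )
                continue
            fpt_res = fpt_variance_filter(
                seg_lat,
                seg_lon,
                seg_t,
                radii=radii,
                var_threshold=fpt_var_threshold,
                metric=fpt_metric,
            )
            max_var = (
                float(np.nanmax(fpt_res.log_fpt_variance))
                if np.any(np.isfinite(fpt_res.log_fpt_variance))
                else np.nan
            )
            if not fpt_res.keep_fishing:
                diagnostics.append(
                    SegmentDecision(b_idx, s, e, mean_cos, False, max_var, "NF-fpt")
                )
                continue
            blab[pts_sl] = LABEL_FISHING
            cand_lat.append(seg_lat)
            cand_lon.append(seg_lon)
            cand_ref.append((b_idx, np.arange(s, e + 1)))
            diagnostics.append(
                SegmentDecision(b_idx, s, e, mean_cos, False, max_var, "F-candidate")
            )

        grid_t.append(gth)
        grid_lab.append(blab)

    # UD correction over the pooled candidate cloud of the whole track
    if cand_lat:
        keep = ud_correct(
            np.concatenate(cand_lat), np.concatenate(cand_lon), isopleth=ud_isopleth
        )
        pos = 0
        for b_idx, idxs in cand_ref:
            k = keep[pos : pos + len(idxs)]
            grid_lab[b_idx][idxs[~k]] = LABEL_NONFISHING
            pos += len(idxs)

    # map grid labels back to the original reports (nearest in time, <= step/2)
    th = track.times_hours
    # account for burst time offsets relative to the track origin
    t0 = track.points["t"].iloc[0]
    for burst, blab in zip(bursts, grid_lab):
        offset = (burst.origin - t0).total_seconds() / 3600.0
        gth = burst.times_hours + offset
        j = np.searchsorted(gth, th)
        j = np.clip(j, 1, len(gth) - 1) if len(gth) > 1 else np.zeros(len(th), dtype=int)
        left = np.abs(th - gth[j - 1]) if len(gth) > 1 else np.abs(th - gth[0])
        right = np.abs(gth[j] - th) if len(gth) > 1 else left
        nearest = np.where(left <= right, j - 1, j) if len(gth) > 1 else np.zeros(len(th), dtype=int)
        dist = np.minimum(left, right)
        within = dist <= step_hours / 2.0 + 1e-9
        fish = within & (blab[nearest] == LABEL_FISHING)
        labels[fish] = LABEL_FISHING

    return _finish(track, labels, shoreline, offshore_km, diagnostics, return_diagnostics)


def _finish(track, labels, shoreline, offshore_km, diagnostics, return_diagnostics):
    from .preprocess import distance_to_shore

    shore = None
    if "shore_km" in track.points.columns and track.points["shore_km"].notna().all():
        shore = track.points["shore_km"].to_numpy(dtype=float)
    elif shoreline is not None:
        shore = np.atleast_1d(
            distance_to_shore(
                track.points["lat"].to_numpy(dtype=float),
                track.points["lon"].to_numpy(dtype=float),
                shoreline,
            )
        )
    if shore is not None:
        labels[shore < offshore_km] = LABEL_NONFISHING
    else:
        logger.warning(
            "track %s lacks shore distances and no shoreline given; "
            "coastal exclusion skipped",
            track.vessel_id,
        )
    if return_diagnostics:
        diag = pd.DataFrame([vars(d) for d in diagnostics])
        return labels, diag
    return labels


class LonglineDetector(BaseEstimator):
    """Estimator wrapper around :func:`detect_longline`.

    Rule-based (no training): ``fit`` records nothing and returns self;
    ``predict`` labels a :class:`~gearsense.tracks.Track`.  Parameters are
    the keyword arguments of :func:`detect_longline`.
    """

    def __init__(
        self,
        step_hours: float = 7.0,
        max_gap_hours: float = 24.0,
        K="auto",
        K_ref: int = 70,
        n_ref_steps: int = 1960,
        Lmin: int = 2,
        cos_threshold: float = 0.8,
        straight_mode: str = "mean",
        fpt_var_threshold: float = 0.1,
        fpt_metric: str = "degrees",
        ud_isopleth: float = 0.95,
        offshore_km: float = 10.0,
        signal: str = "displacement",
    ):
        self.step_hours = step_hours
        self.max_gap_hours = max_gap_hours
        self.K = K
        self.K_ref = K_ref
        self.n_ref_steps = n_ref_steps
        self.Lmin = Lmin
        self.cos_threshold = cos_threshold
        self.straight_mode = straight_mode
        self.fpt_var_threshold = fpt_var_threshold
        self.fpt_metric = fpt_metric
        self.ud_isopleth = ud_isopleth
        self.offshore_km = offshore_km
        self.signal = signal

    def fit(self, X=None, y=None):
        self.is_fitted_ = True
        return self

    def predict(self, track: Track, shoreline: Optional[Shoreline] = None) -> np.ndarray:
        return detect_longline(track, shoreline, **self.get_params())
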