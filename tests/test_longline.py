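"""Longline pipeline: segmentation, straightness, FPT, UD, end-to-end.

Oracles: exhaustive search over admissible breakpoint vectors for the
Lavielle dynamic program, an O(n^2) crossing-time scan for first-passage
times, and direct kernel-sum density evaluation for the UD correction.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from gearsense import (
    annotate,
    classify_straight,
    detect_longline,
    first_passage_times,
    fpt_variance_filter,
    lavielle_segment,
    simulate_longliner,
    turning_cosines,
    ud_correct,
)
from gearsense.longline import LonglineDetector

from conftest import make_track


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_lavielle(x, K, Lmin=2):
    """Exhaustive minimum over all admissible breakpoint vectors."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def cost(i, j):
        return (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / (j - i)

    best, best_bps = np.inf, None
    for bps in itertools.combinations(range(1, n), K - 1):
        bounds = (0, *bps, n)
        if any(b - a < Lmin for a, b in zip(bounds, bounds[1:])):
            continue
        c = sum(cost(a, b) for a, b in zip(bounds, bounds[1:]))
        if c < best:
            best, best_bps = c, bps
    return best, np.asarray(best_bps if best_bps is not None else (), dtype=int)


def brute_fpt(lat, lon, t, i, r):
    """O(n) scan for one point's first-passage time (degree metric)."""
    d = np.hypot(lon - lon[i], lat - lat[i])
    fwd = bwd = None
    for j in range(i + 1, len(d)):
        if d[j] >= r:
            frac = (r - d[j - 1]) / (d[j] - d[j - 1])
            fwd = t[j - 1] + frac * (t[j] - t[j - 1])
            break
    for j in range(i - 1, -1, -1):
        if d[j] >= r:
            frac = (r - d[j + 1]) / (d[j] - d[j + 1])
            bwd = t[j + 1] - frac * (t[j + 1] - t[j])
            break
    if fwd is None or bwd is None:
        return np.nan
    return fwd - bwd


# ---------------------------------------------------------------------------
# Lavielle segmentation
# ---------------------------------------------------------------------------

class TestLavielle:
    def test_constant_series_single_segment(self):
        seg = lavielle_segment(np.full(10, 3.0), K=1)
        assert seg.contrast == pytest.approx(0.0, abs=1e-12)
        assert seg.segments() == [(0, 10)]

    def test_step_change_found_exactly(self):
        x = np.concatenate([np.zeros(10), np.full(10, 5.0)])
        seg = lavielle_segment(x, K=2)
        np.testing.assert_array_equal(seg.breakpoints, [10])
        brute_c, brute_b = brute_lavielle(x, 2)
        assert seg.contrast == pytest.approx(brute_c, abs=1e-9)

    def test_dp_equals_brute_force_k3(self, rng):
        for _ in range(20):
            n = int(rng.integers(12, 31))
            x = rng.normal(0, 1, n) + np.repeat(rng.normal(0, 3, 3), n)[:n]
            seg = lavielle_segment(x, K=3)
            brute_c, brute_b = brute_lavielle(x, 3)
            assert seg.contrast == pytest.approx(brute_c, rel=1e-9)
            np.testing.assert_array_equal(seg.breakpoints, brute_b)

    def test_segments_cover_series_with_min_length(self, rng):
        x = rng.normal(0, 1, 40)
        seg = lavielle_segment(x, K=4, Lmin=3)
        bounds = seg.bounds
        assert bounds[0] == 0 and bounds[-1] == 40
        assert all(b - a >= 3 for a, b in zip(bounds, bounds[1:]))

    def test_infeasible_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            lavielle_segment(np.zeros(5), K=3, Lmin=2)

    def test_deterministic(self, rng):
        x = rng.normal(0, 1, 30)
        a = lavielle_segment(x, K=3)
        b = lavielle_segment(x.copy(), K=3)
        np.testing.assert_array_equal(a.breakpoints, b.breakpoints)


# ---------------------------------------------------------------------------
# Straightness
# ---------------------------------------------------------------------------

class TestStraightness:
    def test_collinear_points_cosine_one(self):
        pts = np.column_stack((np.zeros(6), np.arange(6, dtype=float)))
        np.testing.assert_allclose(turning_cosines(pts), 1.0, atol=1e-12)
        assert classify_straight(pts)

    def test_reversal_cosine_minus_one_is_straight(self):
        # exact back-and-forth: anti-parallel displacement vectors
        lons = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        pts = np.column_stack((np.zeros(5), lons))
        np.testing.assert_allclose(turning_cosines(pts), -1.0, atol=1e-12)
        assert classify_straight(pts)  # the +-0.8 rule catches both signs

    def test_right_angle_zigzag_cosine_zero_is_curved(self):
        # unit steps alternating east/north near the equator
        lat = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        lon = np.array([0.0, 1.0, 1.0, 2.0, 2.0, 3.0])
        pts = np.column_stack((lat, lon))
        np.testing.assert_allclose(turning_cosines(pts), 0.0, atol=0.02)
        assert not classify_straight(pts)

    def test_zero_length_step_counts_as_no_turn(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(turning_cosines(pts), 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            classify_straight(np.zeros((2, 2)))

    def test_majority_mode(self):
        lat = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        lon = np.array([0.0, 1.0, 1.0, 2.0, 2.0, 3.0])
        pts = np.column_stack((lat, lon))
        assert not classify_straight(pts, mode="majority")


# ---------------------------------------------------------------------------
# First-passage time
# ---------------------------------------------------------------------------

class TestFPT:
    def test_straight_constant_speed_analytic(self):
        # eastward along the equator at v deg/h: FPT(r) = 2 r / v
        v = 0.25  # degrees per hour
        t = np.arange(0, 40, 0.5)
        lon = v * t
        lat = np.zeros_like(lon)
        for r in np.linspace(0.1, 1.0, 30):
            fpt = first_passage_times(lat, lon, t, r)
            good = fpt[np.isfinite(fpt)]
            assert len(good) >= 5
            np.testing.assert_allclose(good, 2 * r / v, rtol=1e-6)

    def test_radius_larger_than_path_all_undefined(self):
        t = np.arange(5.0)
        lon = 0.01 * t
        fpt = first_passage_times(np.zeros(5), lon, t, r=1.0)
        assert np.isnan(fpt).all()

    def test_matches_brute_force_on_random_walk(self, rng):
        n = 60
        t = np.arange(n, dtype=float)
        lat = np.cumsum(rng.normal(0, 0.08, n))
        lon = np.cumsum(rng.normal(0, 0.08, n))
        for r in (0.1, 0.3, 0.7):
            ours = first_passage_times(lat, lon, t, r)
            ref = np.array([brute_fpt(lat, lon, t, i, r) for i in range(n)])
            np.testing.assert_allclose(ours, ref, rtol=1e-10, equal_nan=True)

    def test_monotone_in_radius(self, rng):
        n = 50
        t = np.arange(n, dtype=float)
        lat = np.cumsum(rng.normal(0, 0.1, n))
        lon = np.cumsum(rng.normal(0, 0.1, n))
        radii = np.linspace(0.05, 1.0, 12)
        prev = np.full(n, -np.inf)
        for r in radii:
            fpt = first_passage_times(lat, lon, t, r)
            both = np.isfinite(fpt) & np.isfinite(prev)
            assert np.all(fpt[both] >= prev[both] - 1e-9)
            prev = np.where(np.isfinite(fpt), fpt, prev)


class TestFPTVarianceFilter:
    def test_constant_speed_straight_line_relabeled_nf(self):
        v = 0.25
        t = np.arange(0, 40, 0.5)
        lon = v * t
        lat = np.zeros_like(lon)
        res = fpt_variance_filter(lat, lon, t)
        assert not res.keep_fishing
        defined = res.log_fpt_variance[np.isfinite(res.log_fpt_variance)]
        np.testing.assert_allclose(defined, 0.0, atol=1e-9)

    def test_area_restricted_segment_kept(self, rng):
        # tight dwell-transit-dwell structure: widely spread log FPT
        t = np.arange(0, 60, 0.5)
        n = len(t)
        lat = np.zeros(n)
        lon = np.zeros(n)
        third = n // 3
        lon[:third] = 0.02 * rng.standard_normal(third)
        lon[third : 2 * third] = np.linspace(0, 2.0, third)  # fast transit
        lon[2 * third :] = 2.0 + 0.02 * rng.standard_normal(n - 2 * third)
        lat += 0.02 * rng.standard_normal(n)
        res = fpt_variance_filter(lat, lon, t)
        assert res.keep_fishing
        assert np.nanmax(res.log_fpt_variance) > 0.1

    def test_too_few_defined_fpts_conservative(self, caplog):
        t = np.arange(4.0)
        with caplog.at_level("WARNING"):
            res = fpt_variance_filter(np.zeros(4), 0.001 * t, t)
        assert not res.keep_fishing


# ---------------------------------------------------------------------------
# UD correction
# ---------------------------------------------------------------------------

class TestUDCorrect:
    def test_outlier_relabeled(self, rng):
        lat = np.concatenate([rng.normal(0, 0.05, 50), [5.0]])
        lon = np.concatenate([rng.normal(0, 0.05, 50), [5.0]])
        keep = ud_correct(lat, lon, isopleth=0.95)
        assert not keep[-1]
        # direct kernel-sum check: the outlier has the minimum density
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(np.vstack((lon, lat)))
        dens = kde(np.vstack((lon, lat)))
        assert np.argmin(dens) == 50

    def test_isopleth_one_keeps_everything(self, rng):
        lat, lon = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        assert ud_correct(lat, lon, isopleth=1.0).all()

    def test_degenerate_cloud_noop(self, caplog):
        lat = np.zeros(15)
        lon = np.zeros(15)
        with caplog.at_level("WARNING"):
            keep = ud_correct(lat, lon)
        assert keep.all()

    def test_few_candidates_noop(self, rng):
        lat, lon = rng.normal(0, 1, 5), rng.normal(0, 1, 5)
        assert ud_correct(lat, lon).all()


# ---------------------------------------------------------------------------
# End-to-end detector
# ---------------------------------------------------------------------------

class TestDetectLongline:
    def test_pure_transit_all_nf(self, far_shoreline):
        # constant 10 kn due north for 10 days: straight, hence non-fishing
        times = np.arange(0, 240, 0.25)
        lat = -20.0 + (10.0 * times) / 60.0  # 10 kn = 10/60 deg lat per hour
        tr = make_track(times, lat, -120.0, 10.0)
        ann = annotate(tr, far_shoreline)
        labels = detect_longline(ann)
        assert (labels == "NF").all()

    def test_synthetic_longliner_recall(self, far_shoreline):
        track = simulate_longliner(1500, seed=7)
        ann = annotate(track, far_shoreline)
        labels = detect_longline(ann)
        truth = track.points["label"].to_numpy(dtype=object)
        recall = np.mean(labels[truth == "F"] == "F")
        assert recall >= 0.75

    def test_nearshore_forced_nf(self):
        # a fishing-like track entirely within 10 km of the shoreline vertex
        from gearsense import Shoreline

        track = simulate_longliner(400, seed=3)
        df = track.points
        # shoreline vertex grid blanketing the track: every point < 10 km
        shore = Shoreline(
            np.column_stack((df["lat"].to_numpy(), df["lon"].to_numpy()))
        )
        ann = annotate(track, shore)
        assert (ann.points["shore_km"] < 10).all()
        labels = detect_longline(ann)
        assert (labels == "NF").all()

    def test_longitude_translation_invariance(self, far_shoreline):
        track = simulate_longliner(700, seed=11)
        ann = annotate(track, far_shoreline)
        a = detect_longline(ann)
        shifted = ann.copy()
        shifted.points["lon"] = shifted.points["lon"] + 15.0
        shifted.points["shore_km"] = ann.points["shore_km"]  # keep mask equal
        b = detect_longline(shifted)
        np.testing.assert_array_equal(a, b)

    def test_pipeline_is_monotone_in_filters(self, far_shoreline):
        """Each later stage only removes fishing candidates, never adds."""
        track = simulate_longliner(900, seed=5)
        ann = annotate(track, far_shoreline)
        lax = detect_longline(ann, fpt_var_threshold=-1.0, ud_isopleth=1.0)
        strict = detect_longline(ann)
        assert set(np.flatnonzero(strict == "F")) <= set(np.flatnonzero(lax == "F"))

    def test_diagnostics_table(self, far_shoreline):
        track = simulate_longliner(700, seed=2)
        ann = annotate(track, far_shoreline)
        labels, diag = detect_longline(ann, return_diagnostics=True)
        assert {"mean_cos", "decision"} <= set(diag.columns)
        assert len(diag) >= 2

    def test_estimator_wrapper_matches_function(self, far_shoreline):
        track = simulate_longliner(500, seed=9)
        ann = annotate(track, far_shoreline)
        det = LonglineDetector().fit()
        np.testing.assert_array_equal(det.predict(ann), detect_longline(ann))
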