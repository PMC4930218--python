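# Methods

This note documents the models behind each detector, the preprocessing they
share, what the synthetic-track generators do and do not emulate, the
numerical choices, and the known limitations.

## Shared preprocessing

**Distance to shore.** Great-circle (haversine) distance on a sphere of
mean radius 6371.0 km, minimized over a shoreline *vertex* set.  The
spherical model differs from the WGS84 ellipsoid by under 0.6% — irrelevant
at the 10 km exclusion scale — and vertex-based distance means accuracy is
bounded by the shoreline's vertex spacing (a documented limitation, not a
bug: coarse shorelines under-estimate true distance to the coastline
between vertices).  An optional KD-tree path on unit-sphere chords returns
bit-identical values to the exhaustive scan, since chord length is monotone
in central angle.

**Day/night flag.** A point is "day" iff the solar elevation at its
position and UTC time is positive, computed from the standard solar
declination + equation-of-time + hour-angle construction (the truncated
Meeus series used by the NOAA solar calculator; sunrise/sunset timing is
accurate to well under a minute at mid latitudes).  Twilight and refraction
are ignored by default, matching a strict geometric-horizon definition; a
`refraction=True` flag applies the conventional −0.833° apparent-horizon
correction instead.

**Coastal exclusion.** Points closer than `offshore_km` (default 10 km) to
the nearest shoreline vertex are out-of-domain for every detector and
forced NF: vessel movement in and near port is erratic and uninformative.

**Time regularization.** Segmentation requires an evenly sampled series.
Tracks are resampled onto a grid anchored at the first report (default step
7 h — about the duration of a longline set) by *linear interpolation* of
latitude/longitude between the bracketing fixes.  At a 7 h step the
positional error of linear versus great-circle interpolation is dominated
by vessel behavior, not geometry, so the simpler interpolation is used (a
subsampling mode is deliberately not provided; interpolation was the design
choice here).  Gaps longer than `max_gap_hours` (default 24 h) split the
track; nothing is interpolated across them.  Grid speed is defined as
great-circle displacement per step, in knots.

## Trawler: supervised two-state speed HMM

States NF/F, observation = speed over ground.  The joint factorizes as
Pr(S₁)Pr(Y₁|S₁)∏ₜPr(Yₜ|Sₜ)Pr(Sₜ|Sₜ₋₁).  Everything is estimated from
labeled data — there is no Baum–Welch: the transition matrix is
row-normalized label-pair counts (pooled across tracks, never across a
track boundary), the initial distribution is the empirical state frequency,
and emissions are per-state speed histograms with bin width 0.5 kn on
[0, 25.5] kn and additive smoothing α = 1 (AIS speed fields saturate around
25.5 kn; faster reports clip into the top bin).  Histograms are the default
because empirical trawler speed distributions are skewed and heavy-tailed;
a Gaussian emission family is available (`emission="gaussian"`).

Decoding is Viterbi in log space by default; per-point posterior argmax
(forward–backward) is available.  Ties break toward NF — the conservative
direction for an enforcement tool.  Zero-probability emissions (possible
with α = 0) are floored at a configurable log-floor and logged rather than
crashing the decoder.

The 2.5–5.5 kn towing band is *not* hard-coded into the model: the HMM
commits only to speed as the observation, and learns the band from labels.
The band informs the simulator and an optional coastal post-mask.

## Longliner: segmentation + straightness + FPT + UD

Longliner fishing and transit speeds overlap almost completely (lines are
set near steaming speed and hauled along the same leg), so the pipeline
works on movement *geometry* instead:

1. **Signal.** Per-step great-circle displacement (km) of the regularized
   track — the standard speed-like contrast variable in movement ecology.
   Raw grid speed is available via `signal="speed"`.
2. **Lavielle segmentation.** The exact minimizer of the least-squares
   contrast Σ_seg Σᵢ (xᵢ − mean(seg))² over contiguous partitions into K
   segments with length ≥ Lmin = 2, found by dynamic programming (suffix
   recursion; ties resolve to the lexicographically earliest breakpoint
   vector, making results deterministic).  K defaults to `auto`:
   K = round(70 · n_steps / 1960), floored at 2 — i.e. one segment per
   ~28 seven-hour steps, the per-segment budget at which the K = 70 default
   was tuned for multi-month tracks; `K=<int>` overrides.
3. **Straightness.** For each segment, the mean cosine of the turning angle
   at interior grid points (computed on a local planar projection about each
   point; zero-length steps count as "no turn").  Mean above +0.8 *or below
   −0.8* means straight-line movement (forward transit or exact
   back-and-forth) and the whole segment is labeled NF.  A per-point
   majority mode (`straight_mode="majority"`) is provided; the mean rule is
   primary because it is the quantified one.
4. **FPT variance filter.** Curved segments become fishing candidates, but
   curvature alone over-calls fishing.  First-passage time through a circle
   of radius r centered on each point — forward crossing minus backward
   crossing, crossing instants linearly interpolated — is computed at 30
   radii uniform on [0.1, 1] *coordinate degrees* (raw Euclidean distance in
   lon/lat, the convention of the movement-ecology tools this mirrors;
   `fpt_metric="km"` switches to great-circle).  The per-segment variance of
   log FPT across points, maximized over radii, must exceed 0.1, otherwise
   the vessel moves through the segment like a straight line and it is
   relabeled NF.  The variance is taken per segment across points and
   maximized over radii — the variance-peak usage of area-restricted-search
   analysis; segments with fewer than 5 defined FPTs at every radius are
   conservatively NF.
5. **UD correction.** Surviving candidate points from the whole track are
   pooled and a bivariate normal-kernel density (Scott reference-rule
   bandwidth) is fitted on their (lon, lat); points with density below the
   (1 − 0.95) quantile of candidate densities — outside the 95% isopleth,
   the home-range convention — are relabeled NF.  Per-track pooling was
   chosen over per-segment estimation because candidate segments are often
   too small for a stable 2-D density; fewer than 10 candidates or a
   degenerate point cloud makes the stage a logged no-op.

Stages 4 and 5 only ever flip F → NF: the pipeline is monotone, trimming
false alarms, never adding fishing.  Grid labels are mapped back to the
original irregular reports by nearest-in-time assignment within half a
step; unmatched reports and anything inside the coastal exclusion are NF.

## Purse seiner: three-clause filter

`F ⟺ (is_day ∨ ¬require_day) ∧ shore_km ≥ 10 ∧ sog ≤ 2.5 kn`, evaluated
per point with no sequence context (hence idempotent and order-free).  The
speed boundary is inclusive by definition; the offshore boundary is
inclusive by choice (the ambiguity is a single report exactly on the 10 km
ring).  There is deliberately no minimum-event-duration clause.  The
high-speed net-setting phase is not modeled: satellite coverage rarely
samples it, so the filter targets the long, slow haul/bail phase.

## Synthetic track generators

Real S-AIS archives are proprietary, so every detector is exercised on
synthetic tracks whose *behavioral envelopes* are the published gear
kinematics.  The distribution parameters are surrogates — truncated normals
and uniforms chosen to be realistic — because the real per-vessel speed
distributions are unpublished:

* trawler: steaming ~ Normal(12, 1.5) kn truncated at 0; towing speed
  uniform on [2.5, 5.5] kn with duration uniform on [3, 5] h; occasional
  searching (4.5–8 kn) and drift (< 1.5 kn) phases give non-fishing
  behavior that genuinely overlaps the towing band;
* longliner: steaming legs of 24–48 h at ~11.5 kn between grounds, then
  4–9 cycles of set (straight leg at ~9.5 kn, duration lognormal with
  median 6.5 h, log-sd 0.3), soak (drift < 2 kn bridged back to the line's
  end) and haul (retrace of the set leg at ~4.5 kn); set + soak + haul are
  fishing by the gear definition (deployment through retrieval);
* seiner: 0–2 daylight hauls per day (≤ 2.4 kn, 1–3 h), scheduled strictly
  inside the solar-elevation daylight window at the vessel's position, with
  fast (~14 kn) searching and transit otherwise — the resulting fishing
  fraction of points sits in the 2–13% range typical of purse-seine tracks.

Positions are dead-reckoned on a local tangent plane re-projected each
behavioral leg, with additive GPS noise (sd 0.05 km) on reported positions;
report intervals are exponential (mean 8–12 min, floor 2 min); vessels are
tethered to their home basin so multi-week tracks stay regional.  One seed
drives schedule, kinematics, noise and gaps: equal seeds give bit-identical
tracks.  A separate `degrade` operation models satellite coverage dropouts
as random gaps.

**What passing tests on these tracks does and does not show.**  The
generators encode the *same behavioral assumptions the detectors test for*
(that is the point: they provide ground truth where none is public), so
high synthetic scores demonstrate internal correctness — the detector
recovers the pattern it is designed for — not field accuracy.  Real AIS
adds unmodeled structure: mixed gears, weather-driven speed variation,
position spoofing, heavily uneven satellite coverage, and expert-label
noise.  Synthetic performance is an upper bound.

## Evaluation conventions

Following the fisheries-monitoring literature, the non-fishing class plays
the positive role: **sensitivity** = NF recall, **specificity** = F recall,
and Prediction(F)/Prediction(NF) are the class-wise precisions (how often a
point predicted F / NF truly is one).  Ratios with empty denominators are
reported as absent rather than 0 (a track with no true fishing has no
defined specificity).  The identity
accuracy = pct_F · specificity + (1 − pct_F) · sensitivity holds to
rounding and is enforced in tests.

For hard-label predictors the AUC is the single-operating-point trapezoid,
(sensitivity + specificity)/2; when a continuous score is supplied the
rank-based (Mann–Whitney) AUC is used instead.

Fishing effort is the list of per-event durations: one maximal run of
F-labeled points = one event, measured first report to last.  Predicted and
reference effort distributions are compared with a Welch (unequal-variance)
two-sample t-test; fewer than two events on either side makes the test
undefined (reported as absent).

The Monte Carlo harness draws seeded random training windows, fits the
detector on each window and predicts the stretch *immediately after* it, so
tests always run strictly in the training window's future; windows whose
training stretch is one-class are skipped and logged, and over-long
requests are scaled down proportionally with a warning.

## Problem sizes used in the checks

The packaged checks run the trawler HMM on ~5,000-point held-out synthetic
tracks, the longline pipeline on ~1,500 h (≈ 8,000-point) synthetic tracks,
the seiner filter on 20-day tracks, and the Monte Carlo harness at training
windows of 2,000 points with 5,000-point test stretches over 20 windows —
sizes at which every stage's behavior is already asymptotic while the whole
suite stays interactive.

## Known limitations

* Vertex-based shore distance; no polygon containment or EEZ logic.
* No antimeridian normalization beyond track splitting; detectors assume
  tracks do not straddle ±180°.
* The longline K-auto rule ties segment resolution to track length; tracks
  whose fishing/transit alternation is much faster than one segment per
  ~28 steps need an explicit larger K.
* The seiner filter cannot see fishing faster than 2.5 kn, by construction.
* No gear-type identification: each detector assumes its gear is known.
* Simulators have no oceanography (currents, bathymetry, prey fields) and
  no multi-vessel interaction.
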