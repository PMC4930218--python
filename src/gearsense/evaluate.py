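"""Detection metrics, fishing-effort extraction, and Monte Carlo testing.

Naming convention (deliberately mirrored from the fisheries-monitoring
literature this toolkit serves): the *non-fishing* class plays the role of
the positive class, so **sensitivity** is the recall of NF and
**specificity** the recall of F.  ``prediction_F`` / ``prediction_NF`` are
the class-wise precisions (positive/negative predictive values): how often
a point predicted F (resp. NF) truly is one.  Ratios with zero denominators
are reported as ``None`` (e.g. specificity on a track with no fishing at
all).

Fishing effort is the list of per-event durations, one per maximal run of
F-labeled points, measured first report to last report of the run; the
predicted and expert effort distributions are compared with a Welch
two-sample t-test.

The Monte Carlo harness measures a trainable detector's performance under
time variation: for each training size it draws seeded random windows,
trains on the window and predicts the stretch immediately after it, then
dislocates the window, accumulating per-window accuracy/recall/AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import LABEL_FISHING, LABEL_NONFISHING, VALID_LABELS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricsReport:
    """Per-class confusion metrics for one labeled track.

    ``None`` marks an undefined ratio (zero denominator).
    """

    accuracy: float
    sensitivity: Optional[float]  # recall of NF
    specificity: Optional[float]  # recall of F
    prediction_F: Optional[float]  # precision of F
    prediction_NF: Optional[float]  # precision of NF
    auc: Optional[float]
    pct_fishing: float  # truth F fraction
    n: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "prediction_F": self.prediction_F,
            "prediction_NF": self.prediction_NF,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "pct_fishing": self.pct_fishing,
            "n": self.n,
        }


@dataclass(frozen=True)
class EffortComparison:
    """Predicted vs. true fishing-event duration lists and their t-test."""

    effort_pred: np.ndarray
    effort_true: np.ndarray
    t_stat: Optional[float]
    p_value: Optional[float]

    @property
    def significant(self) -> Optional[bool]:
        return None if self.p_value is None else bool(self.p_value < 0.05)


def _check_labels(pred, true):
    pred = np.asarray(pred, dtype=object).ravel()
    true = np.asarray(true, dtype=object).ravel()
    if len(pred) != len(true) or len(pred) == 0:
        raise ValueError("label sequences must have equal length >= 1")
    alien = (set(pred) | set(true)) - set(VALID_LABELS)
    if alien:
        raise ValueError(f"labels outside {{F, NF}}: {sorted(map(str, alien))}")
    return pred, true


def confusion_metrics(pred_labels, true_labels) -> MetricsReport:
    """Confusion-matrix rates with NF as the positive class."""
    pred, true = _check_labels(pred_labels, true_labels)
    n = len(true)
    pf, tf = pred == LABEL_FISHING, true == LABEL_FISHING

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    accuracy = float(np.mean(pf == tf))
    sensitivity = ratio(int(np.sum(~pf & ~tf)), int(np.sum(~tf)))
    specificity = ratio(int(np.sum(pf & tf)), int(np.sum(tf)))
    prediction_F = ratio(int(np.sum(pf & tf)), int(np.sum(pf)))
    prediction_NF = ratio(int(np.sum(~pf & ~tf)), int(np.sum(~pf)))
    auc = None
    if sensitivity is not None and specificity is not None:
        auc = (sensitivity + specificity) / 2.0
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        prediction_F=prediction_F,
        prediction_NF=prediction_NF,
        auc=auc,
        pct_fishing=float(np.mean(tf)),
        n=n,
    )


def auc_binary(pred, true_labels) -> Optional[float]:
    """AUC of a binary or scored predictor against true labels.

    With hard labels, a single-operating-point ROC gives
    (sensitivity + specificity) / 2 (balanced accuracy).  With a continuous
    score (higher = more fishing-like), the rank-based (Mann-Whitney) AUC
    for detecting F is returned.  ``None`` when the truth is one-class.
    """
    true = np.asarray(true_labels, dtype=object).ravel()
    tf = true == LABEL_FISHING
    if tf.all() or not tf.any():
        return None
    pred_arr = np.asarray(pred).ravel()
    if pred_arr.dtype.kind in "fiu" and not set(pred_arr.tolist()) <= {0, 1}:
        score = pred_arr.astype(float)
        nf, nn = int(tf.sum()), int((~tf).sum())
        ranks = stats.rankdata(score)
        u = ranks[tf].sum() - nf * (nf + 1) / 2.0
        return float(u / (nf * nn))
    rep = confusion_metrics(pred, true)
    return rep.auc


def _times_to_hours(times) -> np.ndarray:
    t = np.asarray(times)
    if np.issubdtype(t.dtype, np.number):
        return t.astype(float)
    ts = pd.DatetimeIndex(pd.to_datetime(t, utc=True))
    return ((ts - ts[0]).total_seconds() / 3600.0).to_numpy()


def fishing_effort(labels, times) -> np.ndarray:
    """Per-event fishing durations (hours): one per maximal F-run,
    last report minus first report of the run (0 for single-point events)."""
    labels = np.asarray(labels, dtype=object).ravel()
    th = _times_to_hours(times)
    if len(labels) != len(th):
        raise ValueError("labels and times must align")
    fish = labels == LABEL_FISHING
    if not fish.any():
        return np.empty(0)
    edges = np.diff(fish.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if fish[0]:
        starts = np.concatenate(([0], starts))
    if fish[-1]:
        ends = np.concatenate((ends, [len(fish) - 1]))
    return th[ends] - th[starts]


def compare_effort(pred_labels, true_labels, times) -> EffortComparison:
    """Welch t-test between predicted and expert fishing-event durations.

    Each side needs at least two events for the test; otherwise the
    statistic and p-value are ``None`` (flagged), mirroring tracks with no
    labeled fishing activity at all.
    """
    ep = fishing_effort(pred_labels, times)
    et = fishing_effort(true_labels, times)
    if len(ep) < 2 or len(et) < 2:
        logger.warning(
            "effort comparison not testable: %d predicted / %d true events",
            len(ep), len(et),
        )
        return EffortComparison(ep, et, None, None)
    t_stat, p = stats.ttest_ind(ep, et, equal_var=False)
    if not np.isfinite(t_stat):  # both sides constant and equal
        t_stat, p = 0.0, 1.0
    return EffortComparison(ep, et, float(t_stat), float(p))


def monte_carlo(
    speeds,
    labels,
    trainer: Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]],
    train_sizes: Sequence[int],
    test_size: int = 100_000,
    n_windows: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Sliding-window Monte Carlo evaluation of a trainable detector.

    For each training size, ``n_windows`` window start offsets are drawn
    (seeded); the detector is trained on ``[s, s+train)`` and predicts the
    next ``test_size`` points ``[s+train, s+train+test)`` — always strictly
    in the future of the training window.  If the series is too short for a
    requested size, train and test are scaled down proportionally with a
    warning.  Windows whose training stretch lacks one of the two classes
    are skipped and logged.

    Returns a tidy DataFrame with one row per (train_size, window):
    columns ``train_size, window, start, accuracy, sensitivity,
    specificity, auc``.  Aggregate with :func:`summarize_monte_carlo`.
    """
    speeds = np.asarray(speeds, dtype=float).ravel()
    labels = np.asarray(labels, dtype=object).ravel()
    n = len(speeds)
    rng = np.random.default_rng(seed)
    rows = []
    for requested in train_sizes:
        train, test = int(requested), int(test_size)
        if train + test > n:
            scale = n / (train + test)
            train = max(int(train * scale * 0.999), 2)
            test = max(int(test * scale * 0.999), 1)
            logger.warning(
                "series too short for train=%d test=%d; scaled to %d/%d",
                requested, test_size, train, test,
            )
        starts = rng.integers(0, n - train - test + 1, size=n_windows)
        for w, s in enumerate(starts):
            tr_y = labels[s : s + train]
            if len(set(tr_y)) < 2:
                logger.warning("window %d at %d skipped: one-class training data", w, s)
                continue
            predictor = trainer(speeds[s : s + train], tr_y)
            te_x = speeds[s + train : s + train + test]
            te_y = labels[s + train : s + train + test]
            pred = predictor(te_x)
            rep = confusion_metrics(pred, te_y)
            rows.append(
                {
                    "train_size": requested,
                    "window": w,
                    "start": int(s),
                    "accuracy": rep.accuracy,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    "auc": rep.auc,
                }
            )
    return pd.DataFrame(rows)


def summarize_monte_carlo(results: pd.DataFrame) -> pd.DataFrame:
    """Per-train-size mean and standard deviation of each metric."""
    return results.groupby("train_size")[
        ["accuracy", "sensitivity", "specificity", "auc"]
    ].agg(["mean", "std"])
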