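"""Purse-seiner fishing detection: a multi-layer per-point filter.

Purse seiners haul and bail nearly stationary (speed over ground around
2.5 knots and less), essentially never fish at night, and do not fish in
port or close to shore.  Detection is therefore a pure per-point predicate:

    fishing  iff  daylight  AND  >= 10 km offshore  AND  sog <= 2.5 kn

Both boundaries are inclusive (a report at exactly 2.5 kn or exactly 10 km
offshore counts as fishing).  The high-speed net-setting phase is too brief
to be reliably sampled by satellite AIS and is deliberately not modeled;
the filter captures the haul/bail portion only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .tracks import LABEL_FISHING, LABEL_NONFISHING, Track


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the purse-seine filter.

    speed_max : knots; fishing requires sog <= speed_max (default 2.5).
    offshore_km : km; fishing requires shore_km >= offshore_km (default 10).
    require_day : fishing requires daylight (default True).
    """

    speed_max: float = 2.5
    offshore_km: float = 10.0
    require_day: bool = True

    def __post_init__(self) -> None:
        if self.speed_max <= 0:
            raise ValueError("speed_max must be positive")
        if self.offshore_km < 0:
            raise ValueError("offshore_km must be non-negative")


def detect_seiner(track: Track, params: Optional[FilterParams] = None) -> np.ndarray:
    """Per-point F/NF labels for an annotated purse-seiner track.

    The track must carry non-null ``is_day`` and ``shore_km`` on every point
    (see :func:`gearsense.preprocess.annotate`).  Pure per-point function:
    no sequence context, idempotent.

    Raises
    ------
    ValueError
        Naming the missing annotation field.
    """
    params = params or FilterParams()
    df = track.points
    for fld in ("is_day", "shore_km"):
        if fld not in df.columns or pd.isna(df[fld]).any():
            raise ValueError(f"track {track.vessel_id!r} lacks annotation field {fld!r}")
    sog = df["sog"].to_numpy(dtype=float)
    shore = df["shore_km"].to_numpy(dtype=float)
    day = df["is_day"].to_numpy(dtype=bool)
    fishing = (
        ((~params.require_day) | day)
        & (shore >= params.offshore_km)
        & (sog <= params.speed_max)
    )
    return np.where(fishing, LABEL_FISHING, LABEL_NONFISHING).astype(object)


class SeinerFilter(BaseEstimator):
    """Estimator wrapper around :func:`detect_seiner` (rule-based, no training)."""

    def __init__(
        self,
        speed_max: float = 2.5,
        offshore_km: float = 10.0,
        require_day: bool = True,
    ):
        self.speed_max = speed_max
        self.offshore_km = offshore_km
        self.require_day = require_day

    def fit(self, X=None, y=None):
        self.is_fitted_ = True
        return self

    def predict(self, track: Track) -> np.ndarray:
        return detect_seiner(
            track,
            FilterParams(
                speed_max=self.speed_max,
                offshore_km=self.offshore_km,
                require_day=self.require_day,
            ),
        )
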