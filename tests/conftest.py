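import numpy as np
import pandas as pd
import pytest

from gearsense import Shoreline, Track


def make_track(
    times_h,
    lat,
    lon,
    sog,
    labels=None,
    vessel_id="V1",
    t0="2013-07-01T00:00:00Z",
    **extra_cols,
) -> Track:
    """Build a Track from plain arrays (times in hours after t0)."""
    times_h = np.asarray(times_h, dtype=float)
    n = len(times_h)
    df = pd.DataFrame(
        {
            "t": pd.Timestamp(t0) + pd.to_timedelta(times_h, unit="h"),
            "lat": np.broadcast_to(np.asarray(lat, dtype=float), n),
            "lon": np.broadcast_to(np.asarray(lon, dtype=float), n),
            "sog": np.broadcast_to(np.asarray(sog, dtype=float), n),
        }
    )
    if labels is not None:
        df["label"] = np.asarray(labels, dtype=object)
    for k, v in extra_cols.items():
        df[k] = v
    return Track(vessel_id, df)


@pytest.fixture
def far_shoreline() -> Shoreline:
    """A single shoreline vertex thousands of km from all test positions."""
    return Shoreline(np.array([[65.0, 10.0]]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130701)
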