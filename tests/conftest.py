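import numpy as np
import pandas as pd
import pytest

import daytunes as dt
from daytunes.features import AUDIO_FEATURES


@pytest.fixture(scope="session")
def small_run():
    """A small but complete synthetic run: catalog, events, hourly table,
    fitted 5-subdivision model. Shared across test modules."""
    catalog = dt.generate_track_catalog(8000, dt.default_regime_profiles(), seed=11)
    events = dt.generate_streaming_events(
        catalog, dt.default_weekly_schedule(), 250_000, invalid_frac=0.1, seed=12
    )
    kept = dt.filter_events(events)
    table = dt.aggregate_hourly(kept, catalog)
    normalized, scaler = dt.zscore(table)
    model = dt.fit_subdivisions(normalized, 5, restarts=20, seed=0, scaler=scaler)
    return {
        "catalog": catalog,
        "events": events,
        "table": table,
        "normalized": normalized,
        "scaler": scaler,
        "model": model,
    }


@pytest.fixture()
def toy_catalog():
    """Four hand-written tracks with mid-range features."""
    rows = []
    for i, tempo in enumerate((100.0, 120.0, 140.0, 160.0)):
        row = {f: 0.5 for f in AUDIO_FEATURES}
        row.update(
            track_id=f"t{i}",
            tempo=tempo,
            loudness=-10.0 - i,
            dyn_range_mean=6.0 + i,
            energy=0.4 + 0.1 * i,
        )
        rows.append(row)
    return pd.DataFrame(rows)[["track_id", *AUDIO_FEATURES]]


def make_event(track_id, weekday=0, hour=0, listened=True, seeks=0, valid=True):
    return {
        "session_id": "s0",
        "track_id": track_id,
        "weekday": weekday,
        "hour": hour,
        "listened_most": listened,
        "n_seek_ops": seeks,
        "valid_timestamp": valid,
    }


@pytest.fixture()
def event_row_factory():
    return make_event


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
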