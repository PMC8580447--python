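"""Streaming-event filtering and hour-of-week aggregation.

Playback events are kept only when the listener heard most of the track,
performed at most one seek operation, and the event's date/hour
information is intact. Kept events are binned per unique hour of the
week — hour 1 is Monday 00:00, hour 168 is Sunday 23:00 — and each
audio feature's event-weighted mean and standard deviation is computed
per bin.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .features import AUDIO_FEATURES

logger = logging.getLogger(__name__)

EVENT_COLUMNS = (
    "session_id",
    "track_id",
    "weekday",
    "hour",
    "listened_most",
    "n_seek_ops",
    "valid_timestamp",
)

#: Maximum number of seek operations an event may have and still be kept.
MAX_SEEK_OPS = 1


def hour_of_week(weekday: int, hour: int) -> int:
    """Map (weekday, hour-of-day) to the hour-of-week index in 1..168.

    ``weekday`` is 0 (Monday) .. 6 (Sunday); ``hour`` is 0..23.
    Hour 1 is Monday 00:00 and hour 168 is Sunday 23:00.
    """
    if not 0 <= weekday <= 6:
        raise ValueError(f"weekday must be in 0..6, got {weekday}")
    if not 0 <= hour <= 23:
        raise ValueError(f"hour must be in 0..23, got {hour}")
    return 24 * weekday + hour + 1


def hour_of_week_inverse(h: int) -> tuple[int, int]:
    """Inverse of :func:`hour_of_week`: hour-of-week -> (weekday, hour)."""
    if not 1 <= h <= 168:
        raise ValueError(f"hour-of-week must be in 1..168, got {h}")
    return (h - 1) // 24, (h - 1) % 24


def filter_events(log: pd.DataFrame) -> pd.DataFrame:
    """Keep only analysable playback events.

    An event survives iff the track was listened to the most, it has at
    most one seek-forward/-backward operation, and its timestamp
    (weekday and hour) is present, in range and flagged valid. Malformed
    rows are rejected with a logged reason rather than raising. Row
    order is preserved and the operation is idempotent.
    """
    if log.empty:
        return log.copy()
    missing = [c for c in EVENT_COLUMNS if c not in log.columns]
    if missing:
        raise KeyError(f"event log lacks columns: {missing}")

    weekday = pd.to_numeric(log["weekday"], errors="coerce")
    hour = pd.to_numeric(log["hour"], errors="coerce")
    seeks = pd.to_numeric(log["n_seek_ops"], errors="coerce")

    listened = log["listened_most"].astype(bool)
    ts_ok = (
        log["valid_timestamp"].astype(bool)
        & weekday.between(0, 6)
        & hour.between(0, 23)
        & weekday.notna()
        & hour.notna()
    )
    seeks_ok = seeks.notna() & (seeks <= MAX_SEEK_OPS)

    keep = listened & ts_ok & seeks_ok
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "filter_events: dropped %d/%d events (not-listened=%d, seeks>%d=%d, bad timestamp=%d)",
            n_drop,
            len(log),
            int((~listened).sum()),
            MAX_SEEK_OPS,
            int((~seeks_ok).sum()),
            int((~ts_ok).sum()),
        )
    return log.loc[keep].copy()


def aggregate_hourly(log: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Event-weighted per-hour-of-week feature means and s.d.s.

    Each event contributes its track's audio features once (a track
    streamed twice counts twice). Returns a 168-row DataFrame indexed by
    ``hour_of_week`` with columns ``mean_<feature>``, ``sd_<feature>``
    and ``n_events``; hours with no events hold NaN means/s.d.s and
    ``n_events`` 0. Standard deviations use the population (divide by
    n) convention, matching the z-scoring applied downstream.
    """
    cat = catalog.set_index("track_id")
    unresolved = set(log["track_id"]) - set(cat.index)
    if unresolved:
        shown = sorted(unresolved)[:10]
        raise KeyError(f"{len(unresolved)} event track_ids missing from catalog, e.g. {shown}")

    index = pd.RangeIndex(1, 169, name="hour_of_week")
    out = pd.DataFrame(index=index)
    if log.empty:
        for f in AUDIO_FEATURES:
            out[f"mean_{f}"] = np.nan
            out[f"sd_{f}"] = np.nan
        out["n_events"] = 0
        return out

    how = 24 * log["weekday"].to_numpy(dtype=int) + log["hour"].to_numpy(dtype=int) + 1
    feats = cat.loc[log["track_id"], list(AUDIO_FEATURES)].reset_index(drop=True)
    feats["hour_of_week"] = how

    grouped = feats.groupby("hour_of_week")
    means = grouped.mean().reindex(index)
    sds = grouped.std(ddof=0).reindex(index)
    counts = grouped.size().reindex(index, fill_value=0)

    for f in AUDIO_FEATURES:
        out[f"mean_{f}"] = means[f]
        out[f"sd_{f}"] = sds[f]
    out["n_events"] = counts.astype(int)
    return out


def assert_complete(table: pd.DataFrame) -> None:
    """Raise if any hour of the week has no events (incomplete table)."""
    empty = table.index[table["n_events"] == 0].tolist()
    if empty:
        raise ValueError(f"hourly table has empty hours (no events): {empty[:10]}")
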