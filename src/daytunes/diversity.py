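"""Audio-feature variability vs. diversity of daily activity.

Two 24-hour series are compared. Musical variability: each audio
feature's 168 hourly standard deviations are z-scored across hours,
averaged over the seven days per hour of day, then averaged over
features. Activity diversity: from one-day activity diaries, each hour's
activity proportions are ranked, the top 50 (zero-padded if fewer) give
49 consecutive descending differences, and the index is their median —
a value in [-1, 0], nearer 0 when activity is spread more uniformly.
The two series are compared with a Pearson correlation over the 24
hours of the day.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .features import AUDIO_FEATURES
from .synthetic import MISSING_CODE_MIN, SLEEP_CODES

logger = logging.getLogger(__name__)

TOP_N_ACTIVITIES = 50


def feature_variability(table: pd.DataFrame) -> pd.Series:
    """Mean normalized audio-feature s.d. per hour of the day.

    Per feature, the 168 hourly s.d. values are z-scored across hours
    (population convention); per hour of day the values are averaged
    over the seven days and then over the 15 features. Returns a
    24-value Series indexed by hour of day.
    """
    sds = pd.DataFrame({f: table[f"sd_{f}"] for f in AUDIO_FEATURES})
    if sds.isna().any().any():
        bad = sds.columns[sds.isna().any()].tolist()
        raise ValueError(f"hourly s.d.s contain missing values in {bad}")
    spread = sds.std(ddof=0)
    zero = spread.index[spread == 0].tolist()
    if zero:
        raise ValueError(f"constant s.d. column(s), cannot normalize: {zero}")
    z = (sds - sds.mean()) / spread
    hod = (np.asarray(table.index, dtype=int) - 1) % 24
    per_hour = z.groupby(hod).mean().mean(axis=1)
    per_hour.index.name = "hour"
    return per_hour


def preprocess_diaries(
    diaries: pd.DataFrame, rounding: str = "floor"
) -> pd.DataFrame:
    """Expand minute-level diaries to a person-by-24-hour activity grid.

    Start times are rounded to full hours (``floor``, or ``nearest``)
    and forward-filled so that every hour from a person's first report
    onward carries an activity code. Sleeping codes and missing-data
    codes (>= 500101) are then blanked: those hours contribute nothing
    to hourly counts. Persons left with no valid hour are dropped.
    """
    if rounding not in ("floor", "nearest"):
        raise ValueError("rounding must be 'floor' or 'nearest'")
    grid = pd.DataFrame(
        index=pd.Index(sorted(diaries["person_id"].unique()), name="person_id"),
        columns=range(24),
        dtype=float,
    )
    if diaries.empty:
        return grid
    minutes = diaries["start_minute"].astype(int)
    if rounding == "floor":
        hours = minutes // 60
    else:
        hours = ((minutes + 30) // 60).clip(upper=23)
    tmp = diaries.assign(_hour=hours)
    # last report within an hour defines the hour's activity
    last = tmp.groupby(["person_id", "_hour"])["activity_code"].last().unstack("_hour")
    grid.loc[last.index, last.columns] = last.astype(float)
    grid = grid.ffill(axis=1)

    removable = grid.isin([float(c) for c in SLEEP_CODES]) | (grid >= MISSING_CODE_MIN)
    grid = grid.mask(removable)
    empty = grid.index[grid.isna().all(axis=1)]
    if len(empty):
        logger.info("preprocess_diaries: dropping %d person(s) with no valid hours", len(empty))
        grid = grid.drop(index=empty)
    return grid


def descending_differences(proportions: np.ndarray | list[float]) -> np.ndarray:
    """The 49 consecutive differences of the ranked top-50 proportions.

    Proportions are sorted descending, truncated or zero-padded to 50,
    and differenced (next minus current, hence every value <= 0).
    """
    p = np.sort(np.asarray(proportions, dtype=float))[::-1][:TOP_N_ACTIVITIES]
    padded = np.zeros(TOP_N_ACTIVITIES)
    padded[: len(p)] = p
    return np.diff(padded)


def activity_diversity_index(hour_counts) -> float:
    """Median descending difference of an hour's top-50 activity shares.

    ``hour_counts`` maps activity code to count (mapping, Series or
    array of counts). The result lies in [-1, 0]; an empty hour returns
    NaN (missing).
    """
    if isinstance(hour_counts, pd.Series):
        counts = hour_counts.to_numpy(dtype=float)
    elif isinstance(hour_counts, dict):
        counts = np.fromiter(hour_counts.values(), dtype=float, count=len(hour_counts))
    else:
        counts = np.asarray(hour_counts, dtype=float)
    counts = counts[counts > 0]
    total = counts.sum()
    if counts.size == 0 or total <= 0:
        return float("nan")
    return float(np.median(descending_differences(counts / total)))


def diversity_series(hourly_grid: pd.DataFrame) -> pd.Series:
    """Activity-diversity index per hour of the day from a diary grid."""
    values = {}
    for h in range(24):
        counts = hourly_grid[h].value_counts()
        values[h] = activity_diversity_index(counts)
    out = pd.Series(values, name="activity_diversity")
    out.index.name = "hour"
    return out


def moving_average(series: pd.Series, window: int = 3) -> pd.Series:
    """Circular centered moving average over the 24-hour cycle."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > 23:
        raise ValueError("window must be <= 23")
    v = np.asarray(series, dtype=float)
    if len(v) != 24:
        raise ValueError("series must have 24 values")
    half = window // 2
    extended = np.concatenate([v[-half:], v, v[:half]]) if half else v
    smoothed = np.convolve(extended, np.ones(window) / window, mode="valid")
    return pd.Series(smoothed, index=series.index, name=series.name)


def correlate_diversity_variability(
    diversity: pd.Series, variability: pd.Series
) -> tuple[float, float]:
    """Pearson correlation of the two 24-hour series with two-sided p.

    The p-value comes from the t transform with 22 degrees of freedom.
    """
    d = np.asarray(diversity, dtype=float)
    v = np.asarray(variability, dtype=float)
    if len(d) != 24 or len(v) != 24:
        raise ValueError("both series must have 24 hourly values")
    if np.isnan(d).any() or np.isnan(v).any():
        raise ValueError("series contain missing values")
    if np.std(d) == 0 or np.std(v) == 0:
        raise ValueError("zero variance in a series; correlation undefined")
    r, p = stats.pearsonr(d, v)
    return float(r), float(p)
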