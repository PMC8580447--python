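"""Feature variability, diary preprocessing and the activity-diversity index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import daytunes as dt
from daytunes.diversity import (
    activity_diversity_index,
    correlate_diversity_variability,
    descending_differences,
    feature_variability,
    moving_average,
    preprocess_diaries,
)
from daytunes.features import AUDIO_FEATURES


def sd_table(sd_values):
    """Minimal 168-row hourly table whose sd_ columns all equal sd_values."""
    data = {}
    for f in AUDIO_FEATURES:
        data[f"mean_{f}"] = np.zeros(168)
        data[f"sd_{f}"] = np.asarray(sd_values, dtype=float)
    frame = pd.DataFrame(data, index=pd.RangeIndex(1, 169, name="hour_of_week"))
    frame["n_events"] = 1
    return frame


class TestFeatureVariability:
    def test_constant_sds_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            feature_variability(sd_table(np.ones(168)))

    def test_hour_of_day_ramp_gives_zscored_ramp(self):
        ramp = np.tile(np.arange(24, dtype=float), 7)
        series = feature_variability(sd_table(ramp))
        hours = np.arange(24, dtype=float)
        expected = (hours - hours.mean()) / hours.std()
        assert np.allclose(series.to_numpy(), expected, atol=1e-12)

    def test_night_inflated_spread_peaks_at_night(self, small_run):
        series = feature_variability(small_run["table"])
        night = series[[0, 1, 2, 3, 4, 5]].mean()
        day = series[[10, 11, 12, 13, 14, 15]].mean()
        assert night > day


class TestPreprocessDiaries:
    def test_single_activity_fills_whole_day(self):
        diaries = pd.DataFrame(
            {"person_id": ["p"], "start_minute": [0], "activity_code": [20101]}
        )
        grid = preprocess_diaries(diaries)
        assert (grid.loc["p"] == 20101).all()

    def test_minute_75_rounds_to_hour_one_and_forward_fills(self):
        diaries = pd.DataFrame(
            {
                "person_id": ["p", "p"],
                "start_minute": [75, 300],  # hour 1 and hour 5
                "activity_code": [20101, 20105],
            }
        )
        grid = preprocess_diaries(diaries)
        row = grid.loc["p"]
        assert row[0] != row[0]  # before the first record: nothing
        assert (row[[1, 2, 3, 4]] == 20101).all()
        assert (row[list(range(5, 24))] == 20105).all()

    def test_sleep_only_diary_contributes_nothing(self):
        diaries = pd.DataFrame(
            {"person_id": ["p"], "start_minute": [0], "activity_code": [10101]}
        )
        grid = preprocess_diaries(diaries)
        assert "p" not in grid.index

    def test_missing_codes_blanked_after_fill(self):
        diaries = pd.DataFrame(
            {
                "person_id": ["p", "p"],
                "start_minute": [0, 720],
                "activity_code": [20101, 500101],
            }
        )
        grid = preprocess_diaries(diaries)
        row = grid.loc["p"]
        assert (row[list(range(12))] == 20101).all()
        assert row[list(range(12, 24))].isna().all()

    def test_matches_minute_level_oracle_on_toy_diary(self):
        diaries = pd.DataFrame(
            {
                "person_id": ["a", "a", "a", "b", "b", "c"],
                "start_minute": [0, 150, 900, 0, 59, 30],
                "activity_code": [20101, 10101, 20105, 20107, 20108, 500103],
            }
        )
        grid = preprocess_diaries(diaries)
        # brute force: latest record per floored hour, forward-filled, filters
        for person, rows in diaries.groupby("person_id"):
            expected = {}
            current = None
            records = {int(m) // 60: c for m, c in
                       zip(rows["start_minute"], rows["activity_code"])}
            for h in range(24):
                if h in records:
                    current = records[h]
                code = current
                if code in (10101, 10199, 10102) or (code or 0) >= 500101:
                    code = None
                expected[h] = code
            if all(v is None for v in expected.values()):
                assert person not in grid.index
                continue
            for h in range(24):
                got = grid.loc[person, h]
                if expected[h] is None:
                    assert got != got
                else:
                    assert got == expected[h]


class TestDiversityIndex:
    def test_worked_example_first_difference(self):
        diffs = descending_differences([0.4, 0.3])
        assert diffs[0] == pytest.approx(-0.1)

    def test_fifty_uniform_activities_give_zero(self):
        counts = {code: 2 for code in range(50)}
        assert activity_diversity_index(counts) == 0.0

    def test_three_proportions_padded_median(self):
        # proportions (0.5, 0.3, 0.2): differences (-0.2, -0.1, -0.2, 0 x 46)
        counts = {1: 5, 2: 3, 3: 2}
        assert activity_diversity_index(counts) == 0.0

    def test_empty_hour_is_missing(self):
        assert np.isnan(activity_diversity_index({}))

    def test_invariance_under_relabelling_and_scaling(self, rng):
        counts = {i: int(c) for i, c in enumerate(rng.integers(1, 100, size=30))}
        relabelled = {i + 1000: c for i, c in counts.items()}
        scaled = {i: 7 * c for i, c in counts.items()}
        base = activity_diversity_index(counts)
        assert activity_diversity_index(relabelled) == base
        assert activity_diversity_index(scaled) == pytest.approx(base, abs=1e-12)

    def test_more_uniform_distributions_closer_to_zero(self):
        # nested majorization: progressively flatter 50-activity profiles
        skewed = {i: 51 - i for i in range(50)}
        flatter = {i: 26 for i in range(50)}
        assert activity_diversity_index(flatter) >= activity_diversity_index(skewed)

    @given(st.lists(st.integers(min_value=0, max_value=10**6), min_size=1, max_size=80))
    @settings(max_examples=200, deadline=None)
    def test_index_always_in_range(self, counts):
        value = activity_diversity_index(dict(enumerate(counts)))
        if sum(counts) == 0:
            assert np.isnan(value)
        else:
            assert -1.0 <= value <= 0.0


class TestMovingAverage:
    def test_window_one_is_identity(self):
        s = pd.Series(np.arange(24, dtype=float))
        pd.testing.assert_series_equal(moving_average(s, 1), s)

    def test_constant_series_unchanged(self):
        s = pd.Series(np.full(24, 3.5))
        assert np.allclose(moving_average(s, 5), 3.5)

    def test_impulse_wraps_circularly(self):
        s = pd.Series(np.zeros(24))
        s[0] = 1.0
        out = moving_average(s, 3)
        assert out[23] == pytest.approx(1 / 3)
        assert out[0] == pytest.approx(1 / 3)
        assert out[1] == pytest.approx(1 / 3)
        assert out[2:23].abs().sum() == pytest.approx(0.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            moving_average(pd.Series(np.zeros(24)), 4)


class TestCorrelation:
    def test_perfect_correlation(self):
        d = pd.Series(np.linspace(-1, 0, 24))
        r, p = correlate_diversity_variability(d, d)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        d = pd.Series(np.linspace(-1, 0, 24))
        r, _ = correlate_diversity_variability(d, -d)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        d = pd.Series(rng.normal(size=24))
        v = pd.Series(rng.normal(size=24))
        r, p = correlate_diversity_variability(d, v)
        x, y = d.to_numpy(), v.to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        expected_r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(expected_r, abs=1e-12)
        from scipy import stats as sps

        t = expected_r * np.sqrt(22 / (1 - expected_r**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 22), abs=1e-12)

    def test_zero_variance_rejected(self):
        d = pd.Series(np.zeros(24))
        v = pd.Series(np.linspace(0, 1, 24))
        with pytest.raises(ValueError, match="variance"):
            correlate_diversity_variability(d, v)
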