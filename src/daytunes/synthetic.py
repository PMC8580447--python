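"""Synthetic inputs with planted diurnal structure.

Real analyses of this kind run on streaming-event logs (billions of
playbacks with per-track audio features), time-use diaries and survey
ratings. None of those ship with the package; instead this module
generates inputs carrying the statistical structure the pipeline
assumes — per-hour mixtures of regime-specific audio-feature
distributions with weekday/weekend schedule differences, a controlled
fraction of filter-failing events, diaries with per-hour activity
concentration, and ratings with planted preference effects — together
with ground-truth labels so every downstream stage has a recovery
oracle.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import AUDIO_FEATURES, FEATURE_RANGES

#: Canonical cyclic order of the five within-day subdivisions.
SUBDIVISIONS: tuple[str, ...] = (
    "morning",
    "afternoon",
    "evening",
    "night",
    "late_night",
)

#: ATUS-style 6-digit codes: sleeping (filtered out downstream).
SLEEP_CODES: tuple[int, ...] = (10101, 10199, 10102)
#: Codes at or above this value mark missing/unreported time.
MISSING_CODE_MIN: int = 500101


@dataclass(frozen=True)
class RegimeProfile:
    """Audio-feature distribution of one listening regime.

    Tracks belonging to the regime draw each feature from a normal
    distribution truncated to the feature's documented valid range.
    """

    name: str
    feature_means: dict[str, float]
    feature_sds: dict[str, float]

    def __post_init__(self) -> None:
        for f in self.feature_means:
            if f not in AUDIO_FEATURES:
                raise ValueError(f"unknown audio feature {f!r}")
        missing = set(AUDIO_FEATURES) - set(self.feature_means)
        if missing:
            raise ValueError(f"profile {self.name!r} lacks features {sorted(missing)}")
        for f, sd in self.feature_sds.items():
            if sd < 0:
                raise ValueError(f"{self.name}.{f}: s.d. must be >= 0, got {sd}")
        for f, mu in self.feature_means.items():
            lo, hi = FEATURE_RANGES[f]
            if (lo is not None and mu < lo) or (hi is not None and mu > hi):
                raise ValueError(
                    f"{self.name}.{f}: mean {mu} outside valid range {FEATURE_RANGES[f]}"
                )


@dataclass(frozen=True)
class WeeklySchedule:
    """Assignment of each hour of the week to a mixture of regimes.

    ``assignment`` maps hour-of-week h in 1..168 (h=1 is Monday 00:00)
    to ``{regime_name: weight}`` with weights summing to one. A
    degenerate mixture (single regime, weight 1) is the common case.
    """

    assignment: dict[int, dict[str, float]]

    def __post_init__(self) -> None:
        if set(self.assignment) != set(range(1, 169)):
            raise ValueError("schedule must assign all 168 hours of the week")
        for h, mix in self.assignment.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"hour {h}: mixture weights sum to {total}, not 1")
            if any(w < 0 for w in mix.values()):
                raise ValueError(f"hour {h}: negative mixture weight")

    @property
    def planted_labels(self) -> pd.Series:
        """Dominant regime per hour-of-week (ties broken by name order)."""
        labels = {
            h: max(sorted(mix), key=lambda r: mix[r])
            for h, mix in self.assignment.items()
        }
        return pd.Series(labels, name="regime").sort_index()


@dataclass(frozen=True)
class DiaryProfile:
    """Controls the synthetic time-use diaries.

    ``concentration`` sets how skewed the hourly activity distribution
    is (activity ranked i gets weight exp(-concentration * i)): near 0
    means close to uniform (diverse hours), large means one activity
    dominates. Scalar or one value per hour of the day. Sleep codes are
    ranked first during ``sleep_hours`` so the downstream sleep filter
    has something to remove.
    """

    activity_codes: tuple[int, ...] = field(
        default_factory=lambda: tuple(SLEEP_CODES)
        + tuple(range(20101, 20101 + 54))
        + (500101, 500103)
    )
    # awake activity is more uniform (diverse) in the small hours: low
    # concentration 22:00-05:00, higher during the day
    concentration: float | tuple[float, ...] = field(
        default_factory=lambda: tuple(
            0.02 if h in (22, 23, 0, 1, 2, 3, 4, 5) else 0.06 for h in range(24)
        )
    )
    sleep_hours: tuple[int, ...] = (22, 23, 0, 1, 2, 3, 4, 5, 6)

    def __post_init__(self) -> None:
        conc = np.atleast_1d(np.asarray(self.concentration, dtype=float))
        if conc.size not in (1, 24):
            raise ValueError("concentration must be scalar or length 24")
        if np.any(conc <= 0):
            raise ValueError("concentration must be > 0")
        if not any(c in self.activity_codes for c in SLEEP_CODES):
            raise ValueError("profile must include at least one sleep code")
        if not any(c >= MISSING_CODE_MIN for c in self.activity_codes):
            raise ValueError("profile must include at least one missing-data code")

    def hourly_concentration(self) -> np.ndarray:
        conc = np.atleast_1d(np.asarray(self.concentration, dtype=float))
        return np.full(24, conc[0]) if conc.size == 1 else conc


# ---------------------------------------------------------------------------
# Presets


def default_regime_profiles(separation: float = 1.0) -> list[RegimeProfile]:
    """Five regime profiles following the qualitative centroid structure.

    Relative to a common baseline: mornings are louder, more positive
    and more energetic but slower; afternoons faster with average
    danceability; evenings fastest with peak beat strength, danceability
    and bounciness; nights quietest and slowest with lower energy and
    valence; late night/early morning resembles night with energy and
    valence partly recovered. ``separation`` scales every deviation
    from baseline (>1 gives better-separated regimes).
    """
    base = {
        "energy": 0.64,
        "danceability": 0.62,
        "acousticness": 0.25,
        "dyn_range_mean": 8.0,
        "beat_strength": 0.55,
        "liveness": 0.18,
        "organism": 0.35,
        "mechanism": 0.55,
        "valence": 0.50,
        "bounciness": 0.55,
        "flatness": 0.20,
        "loudness": -8.0,
        "speechiness": 0.10,
        "instrumentalness": 0.15,
        "tempo": 122.5,
    }
    deltas: dict[str, dict[str, float]] = {
        "morning": {
            "loudness": 1.6,
            "valence": 0.07,
            "energy": 0.07,
            "tempo": -3.0,
            "liveness": -0.02,
        },
        "afternoon": {"tempo": 2.0, "loudness": 0.5, "valence": 0.03, "liveness": -0.01},
        "evening": {
            "tempo": 3.5,
            "beat_strength": 0.07,
            "danceability": 0.08,
            "bounciness": 0.07,
            "energy": 0.04,
            "loudness": 1.0,
            "liveness": 0.05,
        },
        "night": {
            "loudness": -3.0,
            "tempo": -4.5,
            "energy": -0.09,
            "valence": -0.08,
            "acousticness": 0.10,
            "flatness": 0.05,
            "liveness": -0.03,
        },
        # resembles night, with energy and valence partly recovered —
        # valence sits above the weekly mean so the late-night threshold
        # signature is distinct from the night's in the selection features
        "late_night": {
            "loudness": -2.0,
            "tempo": -3.0,
            "energy": -0.02,
            "valence": 0.06,
            "acousticness": 0.07,
            "liveness": 0.02,
        },
    }
    sds = {f: 0.18 for f in AUDIO_FEATURES}
    sds.update(
        {
            "dyn_range_mean": 3.0,
            "loudness": 4.0,
            "tempo": 28.0,
            "speechiness": 0.09,
            "instrumentalness": 0.2,
            "liveness": 0.12,
        }
    )
    # musical preference diverges in the small hours: the night and
    # late-night regimes carry a wider within-regime feature spread
    sd_scale = {"morning": 1.0, "afternoon": 1.0, "evening": 1.0,
                "night": 1.35, "late_night": 1.6}
    profiles = []
    for name in SUBDIVISIONS:
        means = dict(base)
        for f, d in deltas[name].items():
            means[f] = means[f] + separation * d
        regime_sds = {f: sd * sd_scale[name] for f, sd in sds.items()}
        profiles.append(
            RegimeProfile(name=name, feature_means=means, feature_sds=regime_sds)
        )
    return profiles


def well_separated_profiles() -> list[RegimeProfile]:
    """Strongly separated regimes for classifier contract checks.

    Deviations from baseline are amplified and within-regime spread
    reduced so that threshold-selected tracks are near-separable in the
    six classifier features.
    """
    profiles = default_regime_profiles(separation=4.0)
    out = []
    for p in profiles:
        sds = {f: sd * 0.45 for f, sd in p.feature_sds.items()}
        out.append(RegimeProfile(p.name, p.feature_means, sds))
    return out


def _daily_blocks() -> dict[int, list[tuple[int, str]]]:
    """Per-weekday (hour-of-day, regime) onset tables for the preset week.

    Weekdays: late night/early morning begins 04:00, morning 06:00,
    afternoon 12:00, evening 20:00, night 23:00. Friday and Saturday
    evenings extend into the small hours, pushing the night onset to
    03:00/04:00 and the late-night onset to 05:00 on the weekend.
    """
    weekday = [(0, "night"), (4, "late_night"), (6, "morning"),
               (12, "afternoon"), (20, "evening"), (23, "night")]
    friday = weekday[:-1]  # evening runs past midnight
    saturday = [(0, "evening"), (3, "night"), (5, "late_night"),
                (6, "morning"), (12, "afternoon"), (20, "evening")]
    sunday = [(0, "evening"), (4, "night"), (5, "late_night"),
              (6, "morning"), (12, "afternoon"), (20, "evening"), (23, "night")]
    return {0: weekday, 1: weekday, 2: weekday, 3: weekday,
            4: friday, 5: saturday, 6: sunday}


#: Mode onset hour-of-day of each regime in the preset week.
PRESET_ONSETS: dict[str, int] = {
    "morning": 6,
    "afternoon": 12,
    "evening": 20,
    "night": 23,
    "late_night": 4,
}


def default_weekly_schedule() -> WeeklySchedule:
    """The five-regime weekly preset with weekday/weekend differences.

    Each hour is assigned a single regime (a degenerate mixture). The
    onset hours are illustrative of commonly observed diurnal listening
    structure, not measurements.
    """
    assignment: dict[int, dict[str, float]] = {}
    for day, blocks in _daily_blocks().items():
        for hod in range(24):
            label = None
            for onset, name in blocks:
                if hod >= onset:
                    label = name
            if label is None:  # before first onset: continuation of prior day
                label = blocks[-1][1]
            assignment[24 * day + hod + 1] = {label: 1.0}
    return WeeklySchedule(assignment=assignment)


# ---------------------------------------------------------------------------
# Generators


def _truncated_normal(
    rng: np.random.Generator, mu: float, sd: float, lo: float | None, hi: float | None, n: int
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mu)
    a = -np.inf if lo is None else (lo - mu) / sd
    b = np.inf if hi is None else (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)


def generate_track_catalog(
    n_tracks: int, profiles: list[RegimeProfile], seed: int
) -> pd.DataFrame:
    """Sample a track catalog from the given regime profiles.

    Each track is assigned a regime uniformly at random and its 15
    features drawn from that regime's truncated normals. Returns a
    DataFrame with ``track_id``, the feature columns, and a
    ``true_regime`` ground-truth column.
    """
    if n_tracks < 0:
        raise ValueError("n_tracks must be >= 0")
    if not profiles:
        raise ValueError("profiles must be non-empty")
    rng = np.random.default_rng(seed)
    regime_idx = rng.integers(0, len(profiles), size=n_tracks)
    data = {f: np.empty(n_tracks) for f in AUDIO_FEATURES}
    for i, prof in enumerate(profiles):
        mask = regime_idx == i
        n = int(mask.sum())
        for f in AUDIO_FEATURES:
            lo, hi = FEATURE_RANGES[f]
            data[f][mask] = _truncated_normal(
                rng, prof.feature_means[f], prof.feature_sds.get(f, 0.0), lo, hi, n
            )
    catalog = pd.DataFrame(data)
    catalog.insert(0, "track_id", [f"t{i:07d}" for i in range(n_tracks)])
    catalog["true_regime"] = [profiles[i].name for i in regime_idx]
    return catalog


def generate_streaming_events(
    catalog: pd.DataFrame,
    schedule: WeeklySchedule,
    n_events: int,
    invalid_frac: float = 0.0,
    seed: int = 0,
    session_length: int = 10,
) -> pd.DataFrame:
    """Simulate a streaming-event log against the weekly schedule.

    Events are spread uniformly over the 168 hours of the week; each
    event draws a regime from its hour's mixture and then a track
    uniformly from that regime's tracks. A fraction ``invalid_frac`` of
    events is made to fail exactly one of the downstream validity
    filters (not listened to the most, more than one seek operation, or
    a corrupt timestamp); the planted validity is recorded in the
    ``true_valid`` ground-truth column.
    """
    if not 0 <= invalid_frac < 1:
        raise ValueError("invalid_frac must be in [0, 1)")
    if n_events > 0 and len(catalog) == 0:
        raise ValueError("cannot generate events from an empty catalog")
    rng = np.random.default_rng(seed)

    regime_names = sorted(catalog["true_regime"].unique()) if len(catalog) else []
    tracks_by_regime = {
        r: catalog.index[catalog["true_regime"] == r].to_numpy() for r in regime_names
    }

    hours = rng.integers(1, 169, size=n_events)
    track_rows = np.empty(n_events, dtype=int)
    for h in range(1, 169):
        mask = hours == h
        n_h = int(mask.sum())
        if n_h == 0:
            continue
        mix = schedule.assignment[h]
        names = sorted(mix)
        weights = np.array([mix[r] for r in names])
        chosen = rng.choice(len(names), size=n_h, p=weights / weights.sum())
        rows = np.empty(n_h, dtype=int)
        for j, r in enumerate(names):
            sub = chosen == j
            if not sub.any():
                continue
            pool = tracks_by_regime.get(r)
            if pool is None or len(pool) == 0:
                raise ValueError(f"no catalog tracks for regime {r!r} needed at hour {h}")
            rows[sub] = rng.choice(pool, size=int(sub.sum()))
        track_rows[mask] = rows

    weekday = (hours - 1) // 24
    hod = (hours - 1) % 24
    listened_most = np.ones(n_events, dtype=bool)
    n_seek_ops = rng.integers(0, 2, size=n_events)  # 0 or 1: both pass the filter
    valid_timestamp = np.ones(n_events, dtype=bool)

    invalid = rng.random(n_events) < invalid_frac
    mode = rng.integers(0, 3, size=n_events)
    listened_most[invalid & (mode == 0)] = False
    sel = invalid & (mode == 1)
    n_seek_ops[sel] = rng.integers(2, 6, size=int(sel.sum()))
    valid_timestamp[invalid & (mode == 2)] = False

    log = pd.DataFrame(
        {
            "session_id": [f"s{i // session_length:08d}" for i in range(n_events)],
            "track_id": catalog["track_id"].to_numpy()[track_rows],
            "weekday": weekday,
            "hour": hod,
            "listened_most": listened_most,
            "n_seek_ops": n_seek_ops,
            "valid_timestamp": valid_timestamp,
            "true_valid": ~invalid,
            "true_regime": catalog["true_regime"].to_numpy()[track_rows],
        }
    )
    return log


def generate_activity_diaries(
    n_people: int, profile: DiaryProfile | None = None, seed: int = 0
) -> pd.DataFrame:
    """Simulate one diary day per person at sub-hour resolution.

    Each person reports a first activity at minute 0 and thereafter
    starts a new activity in any given hour with probability 0.7, at a
    uniformly random minute within the hour — exercising the downstream
    rounding and forward-fill. Activities are drawn from a per-hour
    ranked distribution whose skew is set by the profile's
    concentration; sleep codes are ranked first during sleep hours.

    Returns a DataFrame (person_id, start_minute, activity_code).
    """
    if n_people < 0:
        raise ValueError("n_people must be >= 0")
    profile = profile or DiaryProfile()
    rng = np.random.default_rng(seed)
    codes = np.asarray(profile.activity_codes)
    conc = profile.hourly_concentration()

    # per-hour ranked weights: rank i gets exp(-concentration * i)
    probs = np.empty((24, len(codes)))
    sleep_first = np.concatenate(
        [
            [i for i, c in enumerate(codes) if c in SLEEP_CODES],
            [i for i, c in enumerate(codes) if c not in SLEEP_CODES],
        ]
    ).astype(int)
    sleep_last = np.concatenate(
        [
            [i for i, c in enumerate(codes) if c not in SLEEP_CODES],
            [i for i, c in enumerate(codes) if c in SLEEP_CODES],
        ]
    ).astype(int)
    for h in range(24):
        order = sleep_first if h in profile.sleep_hours else sleep_last
        w = np.exp(-conc[h] * np.arange(len(codes)))
        p = np.empty(len(codes))
        p[order] = w
        probs[h] = p / p.sum()

    records: list[tuple[str, int, int]] = []
    for p_idx in range(n_people):
        pid = f"p{p_idx:06d}"
        for h in range(24):
            starts_new = h == 0 or rng.random() < 0.7
            if not starts_new:
                continue
            minute = 0 if h == 0 else int(h * 60 + rng.integers(0, 60))
            code = int(rng.choice(codes, p=probs[h]))
            records.append((pid, minute, code))
    return pd.DataFrame(records, columns=["person_id", "start_minute", "activity_code"])


def generate_ratings(
    n_participants: int,
    effects: dict[str, float] | None = None,
    noise_sd: float = 20.0,
    missing_frac: float = 0.0,
    seed: int = 0,
    participant_sd: float = 8.0,
) -> pd.DataFrame:
    """Simulate the single-track preference survey.

    Fifteen tracks (three per subdivision) are each rated by every
    participant once per candidate subdivision on a 1–101 slider. A
    track's rating at its own subdivision's slot carries the planted
    effect for that subdivision; all ratings share a participant
    baseline and Gaussian noise, then clip to [1, 101]. Whole tracks go
    unrated with probability ``missing_frac`` to exercise downstream
    participant exclusion.
    """
    if n_participants < 0:
        raise ValueError("n_participants must be >= 0")
    if not 0 <= missing_frac <= 1:
        raise ValueError("missing_frac must be in [0, 1]")
    effects = dict.fromkeys(SUBDIVISIONS, 0.0) | (effects or {})
    unknown = set(effects) - set(SUBDIVISIONS)
    if unknown:
        raise ValueError(f"unknown subdivisions in effects: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    track_ids = np.array([f"r{i:02d}" for i in range(15)])
    track_subs = np.array([SUBDIVISIONS[i // 3] for i in range(15)])
    slots = np.array(SUBDIVISIONS)
    effect_grid = np.where(
        track_subs[:, None] == slots[None, :],
        np.array([effects[s] for s in track_subs])[:, None],
        0.0,
    )  # (15 tracks, 5 slots)

    baselines = (
        rng.normal(0.0, participant_sd, size=n_participants)
        if participant_sd > 0
        else np.zeros(n_participants)
    )
    rated = rng.random((n_participants, 15)) >= missing_frac
    noise = (
        rng.normal(0.0, noise_sd, size=(n_participants, 15, 5))
        if noise_sd > 0
        else np.zeros((n_participants, 15, 5))
    )
    ratings = np.clip(
        51.0 + baselines[:, None, None] + effect_grid[None, :, :] + noise, 1.0, 101.0
    )

    p_idx, t_idx, s_idx = np.nonzero(rated[:, :, None] & np.ones((1, 1, 5), dtype=bool))
    return pd.DataFrame(
        {
            "participant_id": np.array([f"q{i:05d}" for i in range(n_participants)])[p_idx],
            "track_id": track_ids[t_idx],
            "subdivision": track_subs[t_idx],
            "rated_subdivision": slots[s_idx],
            "rating": ratings[p_idx, t_idx, s_idx],
        }
    )
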