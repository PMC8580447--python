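"""Audio-feature vocabulary and valid ranges.

Streaming catalogs describe each track by 15 scalar audio features
(energy, danceability, tempo, ...). Most are bounded in [0, 1]; loudness
and the mean dynamic range are in decibels, tempo in beats per minute.
Loudness is nominally bounded above by 0 dBFS but positive values occur
in real catalogs, so its upper bound is not enforced on ingest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical feature order used everywhere (catalog columns, centroids).
AUDIO_FEATURES: tuple[str, ...] = (
    "energy",
    "danceability",
    "acousticness",
    "dyn_range_mean",
    "beat_strength",
    "liveness",
    "organism",
    "mechanism",
    "valence",
    "bounciness",
    "flatness",
    "loudness",
    "speechiness",
    "instrumentalness",
    "tempo",
)

#: Inclusive (low, high) validity bounds; None means unbounded on that side.
#: ``enforced`` marks bounds checked on ingest — loudness values above the
#: nominal 0 dBFS ceiling occur in the wild and are admitted.
FEATURE_RANGES: dict[str, tuple[float | None, float | None]] = {
    "energy": (0.0, 1.0),
    "danceability": (0.0, 1.0),
    "acousticness": (0.0, 1.0),
    "dyn_range_mean": (0.0, None),  # dB, positive
    "beat_strength": (0.0, 1.0),
    "liveness": (0.0, 1.0),
    "organism": (0.0, 1.0),
    "mechanism": (0.0, 1.0),
    "valence": (0.0, 1.0),
    "bounciness": (0.0, 1.0),
    "flatness": (0.0, 1.0),
    "loudness": (-60.0, None),  # dBFS; positive values admitted
    "speechiness": (0.0, 1.0),
    "instrumentalness": (0.0, 1.0),
    "tempo": (0.0, None),  # BPM, strictly positive in practice
}

#: Features bounded in [0, 1].
UNIT_FEATURES: tuple[str, ...] = tuple(
    f for f in AUDIO_FEATURES if FEATURE_RANGES[f] == (0.0, 1.0)
)


@dataclass(frozen=True)
class AudioFeatureVector:
    """One track's audio features, validated against the documented ranges."""

    energy: float
    danceability: float
    acousticness: float
    dyn_range_mean: float
    beat_strength: float
    liveness: float
    organism: float
    mechanism: float
    valence: float
    bounciness: float
    flatness: float
    loudness: float
    speechiness: float
    instrumentalness: float
    tempo: float

    def __post_init__(self) -> None:
        for name in AUDIO_FEATURES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
            lo, hi = FEATURE_RANGES[name]
            if lo is not None and value < lo:
                raise ValueError(f"{name}={value} below valid range (min {lo})")
            if hi is not None and value > hi:
                raise ValueError(f"{name}={value} above valid range (max {hi})")
        if self.tempo <= 0:
            raise ValueError(f"tempo must be > 0, got {self.tempo}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in AUDIO_FEATURES], dtype=float)

    @classmethod
    def from_mapping(cls, mapping) -> "AudioFeatureVector":
        return cls(**{f: float(mapping[f]) for f in AUDIO_FEATURES})


def validate_feature_frame(frame: pd.DataFrame) -> pd.Series:
    """Row-wise validity mask for a DataFrame with the 15 feature columns.

    Returns a boolean Series (True = all features inside their documented
    ranges). Missing feature columns raise ``KeyError``.
    """
    missing = [f for f in AUDIO_FEATURES if f not in frame.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    ok = pd.Series(True, index=frame.index)
    for name in AUDIO_FEATURES:
        col = pd.to_numeric(frame[name], errors="coerce")
        good = np.isfinite(col)
        lo, hi = FEATURE_RANGES[name]
        if lo is not None:
            good &= col >= lo
        if hi is not None:
            good &= col <= hi
        if name == "tempo":
            good &= col > 0
        ok &= good
    return ok
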