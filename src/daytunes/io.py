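"""Readers, writers and validators for the pipeline's file formats.

All tables are UTF-8 comma-separated CSV with a mandatory header row
and '.' decimals; event logs may alternatively be NDJSON (one JSON
object per line). Generators' ground-truth labels travel in a JSON
sidecar next to the main file (``<name>.truth.json``) so that analysis
inputs stay schema-clean.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import AUDIO_FEATURES, validate_feature_frame
from .streams import EVENT_COLUMNS

CATALOG_COLUMNS = ("track_id", *AUDIO_FEATURES)
DIARY_COLUMNS = ("person_id", "start_minute", "activity_code")
RATING_COLUMNS = ("participant_id", "track_id", "subdivision", "rated_subdivision", "rating")

_TRUTH_COLUMNS = ("true_regime", "true_valid")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".truth.json")


def _split_truth(frame: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    truth = {c: frame[c].tolist() for c in _TRUTH_COLUMNS if c in frame.columns}
    return frame.drop(columns=list(truth)), truth


def _merge_truth(frame: pd.DataFrame, path: Path) -> pd.DataFrame:
    sidecar = _sidecar(path)
    if sidecar.exists():
        truth = json.loads(sidecar.read_text())
        for col, values in truth.items():
            if len(values) == len(frame):
                frame[col] = values
    return frame


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    public, truth = _split_truth(catalog)
    public[list(CATALOG_COLUMNS)].to_csv(path, index=False)
    if truth:
        _sidecar(path).write_text(json.dumps(truth))


def read_catalog(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in CATALOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"catalog {path} lacks columns {missing}")
    return _merge_truth(frame, path)


def write_events(log: pd.DataFrame, path: str | Path) -> None:
    """Write an event log as CSV, or NDJSON if the suffix is .ndjson."""
    path = Path(path)
    public, truth = _split_truth(log)
    public = public[list(EVENT_COLUMNS)]
    if path.suffix == ".ndjson":
        path.write_text(public.to_json(orient="records", lines=True))
    else:
        public.to_csv(path, index=False)
    if truth:
        _sidecar(path).write_text(json.dumps(truth))


def read_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".ndjson":
        frame = pd.read_json(path, orient="records", lines=True)
    else:
        frame = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"event log {path} lacks columns {missing}")
    return _merge_truth(frame, path)


def write_hourly_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = [f"mean_{f}" for f in AUDIO_FEATURES] + [f"sd_{f}" for f in AUDIO_FEATURES]
    cols += ["n_events"]
    table[cols].to_csv(path, index=True, index_label="hour_of_week")


def read_hourly_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="hour_of_week")
    if len(table) != 168:
        raise ValueError(f"hourly table must have 168 rows, found {len(table)}")
    return table


def write_diaries(diaries: pd.DataFrame, path: str | Path) -> None:
    diaries[list(DIARY_COLUMNS)].to_csv(path, index=False)


def read_diaries(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in DIARY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"diary table {path} lacks columns {missing}")
    return frame


def write_ratings(ratings: pd.DataFrame, path: str | Path) -> None:
    ratings[list(RATING_COLUMNS)].to_csv(path, index=False)


def read_ratings(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in RATING_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"ratings table {path} lacks columns {missing}")
    return frame


def write_series(series: pd.Series, path: str | Path, name: str) -> None:
    series.rename(name).to_csv(path, index_label="hour")


def read_series(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, index_col="hour")
    return frame.iloc[:, 0]


# ---------------------------------------------------------------------------
# Validation


def validate_inputs(path: str | Path, schema_name: str) -> dict:
    """Per-row schema and range checks for an input file.

    ``schema_name`` is one of ``catalog``, ``events``, ``diaries``,
    ``ratings``. Returns a report dict with total rows, rejected row
    count and per-reason counts; raises on unreadable files or unknown
    schemas.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reasons: dict[str, int] = {}

    def count(mask: pd.Series, reason: str) -> None:
        n = int(mask.sum())
        if n:
            reasons[reason] = reasons.get(reason, 0) + n

    if schema_name == "catalog":
        frame = read_catalog(path)
        ok = validate_feature_frame(frame)
        count(~ok, "audio feature out of documented range")
        count(frame["track_id"].duplicated(), "duplicate track_id")
        rejected = int((~ok | frame["track_id"].duplicated()).sum())
    elif schema_name == "events":
        frame = read_events(path)
        weekday = pd.to_numeric(frame["weekday"], errors="coerce")
        hour = pd.to_numeric(frame["hour"], errors="coerce")
        seeks = pd.to_numeric(frame["n_seek_ops"], errors="coerce")
        bad_wd = ~weekday.between(0, 6) | weekday.isna()
        bad_h = ~hour.between(0, 23) | hour.isna()
        bad_seek = seeks.isna() | (seeks < 0)
        count(bad_wd, "weekday out of range")
        count(bad_h, "hour out of range")
        count(bad_seek, "invalid seek count")
        rejected = int((bad_wd | bad_h | bad_seek).sum())
    elif schema_name == "diaries":
        frame = read_diaries(path)
        minute = pd.to_numeric(frame["start_minute"], errors="coerce")
        code = pd.to_numeric(frame["activity_code"], errors="coerce")
        bad_min = ~minute.between(0, 1439) | minute.isna()
        bad_code = code.isna() | (code <= 0)
        count(bad_min, "start_minute out of range")
        count(bad_code, "invalid activity code")
        rejected = int((bad_min | bad_code).sum())
    elif schema_name == "ratings":
        frame = read_ratings(path)
        rating = pd.to_numeric(frame["rating"], errors="coerce")
        bad_rating = ~rating.between(1, 101) | rating.isna()
        dup = frame.duplicated(["participant_id", "track_id", "rated_subdivision"])
        count(bad_rating, "rating outside slider range 1-101")
        count(dup, "duplicate (participant, track, slot) rating")
        rejected = int((bad_rating | dup).sum())
    else:
        raise ValueError(f"unknown schema {schema_name!r}")

    return {
        "path": str(path),
        "schema": schema_name,
        "n_rows": int(len(frame)),
        "n_rejected": rejected,
        "reasons": reasons,
    }


def file_sha256(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
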