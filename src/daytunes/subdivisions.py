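"""Discovery of within-day listening subdivisions.

The 168 hourly audio-feature means are z-scored per feature, clustered
with k-means over a range of k, and the number of clusters chosen where
the inertia curve bends (maximum distance to the chord joining the
curve's endpoints, both axes min-max scaled). The fitted partition is
summarised as a :class:`SubdivisionModel`: per-hour labels, a check
that the clusters occur in the same cyclic order every day, each
cluster's modal onset hour with a circular s.d., and centroid profiles
on the normalized and raw scales, including each cluster's deviation
from the weekly grand mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .features import AUDIO_FEATURES
from .streams import assert_complete
from .synthetic import SUBDIVISIONS


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature mean/s.d. of the 168 hourly means, for z = (x-u)/s."""

    mean: pd.Series
    sd: pd.Series

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        return (frame - self.mean) / self.sd

    def inverse(self, frame: pd.DataFrame) -> pd.DataFrame:
        return frame * self.sd + self.mean


def _mean_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Extract the hourly-mean block as plain feature-named columns."""
    cols = {f: table[f"mean_{f}"] for f in AUDIO_FEATURES if f"mean_{f}" in table}
    if not cols:
        # already a plain feature table
        return table[[f for f in AUDIO_FEATURES if f in table.columns]].copy()
    return pd.DataFrame(cols)


def zscore(table: pd.DataFrame) -> tuple[pd.DataFrame, ScalerParams]:
    """Z-score each feature's hourly means across the 168 hours.

    Uses the population convention z = (x - u) / s with s the population
    s.d. Raises on missing hours and on constant columns (which cannot
    be scaled), naming the offending feature.
    """
    if "n_events" in table.columns:
        assert_complete(table)
    means = _mean_columns(table)
    if means.isna().any().any():
        bad = means.columns[means.isna().any()].tolist()
        raise ValueError(f"hourly means contain missing values in {bad}")
    u = means.mean()
    s = means.std(ddof=0)
    zero = s.index[s == 0].tolist()
    if zero:
        raise ValueError(f"constant feature column(s), cannot z-score: {zero}")
    params = ScalerParams(mean=u, sd=s)
    return params.transform(means), params


def kmeans_scan(
    normalized: pd.DataFrame,
    k_range: tuple[int, int] = (2, 24),
    restarts: int = 20,
    max_iter: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Best-of-restarts inertia for each k in ``k_range`` (inclusive).

    Returns a DataFrame with columns ``k`` and ``inertia`` plus the
    restarts/seed recorded as attrs. k beyond the number of distinct
    rows is an error.
    """
    X = normalized.to_numpy(dtype=float)
    n_distinct = len(np.unique(X, axis=0))
    lo, hi = k_range
    if hi > n_distinct:
        raise ValueError(f"k_range upper bound {hi} exceeds {n_distinct} distinct rows")
    rows = []
    for k in range(lo, hi + 1):
        km = KMeans(n_clusters=k, n_init=restarts, max_iter=max_iter, random_state=seed)
        km.fit(X)
        rows.append((k, float(km.inertia_)))
    curve = pd.DataFrame(rows, columns=["k", "inertia"])
    curve.attrs.update({"restarts": restarts, "max_iter": max_iter, "seed": seed})
    return curve


def select_k_elbow(curve: pd.DataFrame) -> int:
    """Choose k at the elbow of the inertia curve.

    Both axes are min-max scaled to [0, 1]; the selected k maximizes
    the perpendicular distance from its point to the chord joining the
    first and last points. Only interior points are eligible (the chord
    passes through the endpoints); ties resolve to the smallest k.
    """
    if len(curve) < 3:
        raise ValueError("elbow selection needs at least 3 (k, inertia) points")
    k = curve["k"].to_numpy(dtype=float)
    inertia = curve["inertia"].to_numpy(dtype=float)
    if not np.all(np.diff(k) > 0):
        raise ValueError("k values must be strictly increasing")

    def minmax(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        return np.zeros_like(v) if span == 0 else (v - v.min()) / span

    x, y = minmax(k), minmax(inertia)
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    # distance from (x,y) to the chord through (x0,y0)-(x1,y1)
    norm = np.hypot(x1 - x0, y1 - y0)
    dist = np.abs((x1 - x0) * (y0 - y) - (x0 - x) * (y1 - y0)) / norm
    interior = dist[1:-1]
    # ties (within float tolerance) resolve to the smallest k
    best = int(np.flatnonzero(interior >= interior.max() - 1e-12)[0]) + 1
    return int(curve["k"].iloc[best])


def grand_mean_profile(table: pd.DataFrame) -> pd.Series:
    """Per-feature mean over the 168 hourly means (hours unweighted)."""
    return _mean_columns(table).mean()


# ---------------------------------------------------------------------------
# Subdivision model


@dataclass
class ClusterSummary:
    """One subdivision's temporal and audio-feature summary."""

    name: str
    mode_onset: int  # hour of day 0..23
    onset_sd: float  # circular s.d. of run-onset hours, in hours
    mode_offset: int  # last hour of day of the run, mode over runs
    n_hours: int
    centroid_normalized: pd.Series
    centroid_raw: pd.Series
    centroid_raw_sd: pd.Series  # s.d. of member hourly means, raw scale
    relative_profile: pd.Series  # centroid_raw - grand mean


@dataclass
class SubdivisionModel:
    k: int
    labels: pd.Series  # hour_of_week (1..168) -> canonical cluster id 1..k
    clusters: list[ClusterSummary]  # indexed by canonical id - 1
    cyclic_order_ok: bool
    grand_mean: pd.Series
    seed: int = 0
    restarts: int = 20

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.clusters]

    def named_labels(self) -> pd.Series:
        mapping = {i + 1: c.name for i, c in enumerate(self.clusters)}
        return self.labels.map(mapping)

    def cluster(self, name: str) -> ClusterSummary:
        for c in self.clusters:
            if c.name == name:
                return c
        raise KeyError(name)

    def relative_profile_matrix(self) -> pd.DataFrame:
        return pd.DataFrame({c.name: c.relative_profile for c in self.clusters}).T

    def to_json(self) -> str:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "restarts": self.restarts,
            "cyclic_order_ok": self.cyclic_order_ok,
            "labels": self.labels.tolist(),
            "grand_mean": self.grand_mean.to_dict(),
            "clusters": [
                {
                    "name": c.name,
                    "mode_onset": c.mode_onset,
                    "onset_sd": c.onset_sd,
                    "mode_offset": c.mode_offset,
                    "n_hours": c.n_hours,
                    "centroid_normalized": c.centroid_normalized.to_dict(),
                    "centroid_raw": c.centroid_raw.to_dict(),
                    "centroid_raw_sd": c.centroid_raw_sd.to_dict(),
                    "relative_profile": c.relative_profile.to_dict(),
                }
                for c in self.clusters
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SubdivisionModel":
        d = json.loads(text)
        clusters = [
            ClusterSummary(
                name=c["name"],
                mode_onset=c["mode_onset"],
                onset_sd=c["onset_sd"],
                mode_offset=c["mode_offset"],
                n_hours=c["n_hours"],
                centroid_normalized=pd.Series(c["centroid_normalized"]),
                centroid_raw=pd.Series(c["centroid_raw"]),
                centroid_raw_sd=pd.Series(c["centroid_raw_sd"]),
                relative_profile=pd.Series(c["relative_profile"]),
            )
            for c in d["clusters"]
        ]
        labels = pd.Series(d["labels"], index=pd.RangeIndex(1, 169, name="hour_of_week"))
        return cls(
            k=d["k"],
            labels=labels,
            clusters=clusters,
            cyclic_order_ok=d["cyclic_order_ok"],
            grand_mean=pd.Series(d["grand_mean"]),
            seed=d["seed"],
            restarts=d["restarts"],
        )


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Circular runs of equal labels over the 168-hour week.

    Returns (label, start_index, length) with start_index in 0..167;
    a run may wrap past Sunday 23:00 into Monday.
    """
    n = len(labels)
    starts = [i for i in range(n) if labels[i] != labels[i - 1]]
    if not starts:  # single label everywhere
        return [(int(labels[0]), 0, n)]
    runs = []
    for j, s in enumerate(starts):
        nxt = starts[(j + 1) % len(starts)]
        length = (nxt - s) % n or n
        runs.append((int(labels[s]), s, length))
    return runs


def _mode_with_earliest_tie(values: list[int]) -> int:
    counts = pd.Series(values).value_counts()
    top = counts.max()
    return int(min(v for v, c in counts.items() if c == top))


def _circular_sd_hours(hours: list[int]) -> float:
    if len(hours) <= 1:
        return 0.0
    radians = np.asarray(hours, dtype=float) * 2 * np.pi / 24
    return float(stats.circstd(radians) * 24 / (2 * np.pi))


def _check_cyclic_order(labels: np.ndarray) -> bool:
    """True iff the clusters occur in one consistent cyclic order.

    Over the circular 168-hour week, the sequence of cluster runs must
    be generated by a single cycle through all k labels: every cluster
    is always followed by the same next cluster. This is the week-level
    form of "each day shows the same rotation of subdivisions" and,
    unlike a per-calendar-day check, tolerates runs that cross midnight
    (e.g. a weekend evening extending into the small hours).
    """
    run_labels = [lab for lab, _, _ in _runs(labels)]
    k = len(set(labels.tolist()))
    if len(run_labels) < 2:
        return k == 1
    successor: dict[int, int] = {}
    for i, lab in enumerate(run_labels):
        nxt = run_labels[(i + 1) % len(run_labels)]
        if successor.setdefault(lab, nxt) != nxt:
            return False
    # the successor map must form one cycle covering all k labels
    start = run_labels[0]
    seen = {start}
    cur = start
    while True:
        cur = successor[cur]
        if cur == start:
            break
        if cur in seen:
            return False
        seen.add(cur)
    return len(seen) == k


def fit_subdivisions(
    normalized: pd.DataFrame,
    k: int,
    restarts: int = 20,
    max_iter: int = 1000,
    seed: int = 0,
    scaler: ScalerParams | None = None,
) -> SubdivisionModel:
    """Cluster the normalized hourly table and summarise the partition.

    Clusters are canonicalized by modal onset hour, anchored at the
    cluster whose onset is nearest 06:00 and proceeding in onset order
    around the clock; with k = 5 the canonical names morning, afternoon,
    evening, night and late night/early morning apply, otherwise
    clusters are named ``subdiv_i``. Onsets are the hours of day at
    which each circular run of the cluster begins; the modal onset
    breaks ties toward the earlier hour and its spread is a circular
    s.d. in hours. A cluster's offset is the last hour of day of its
    runs (mode), i.e. the hour before the next cluster's onset.
    """
    X = normalized.to_numpy(dtype=float)
    if len(X) != 168:
        raise ValueError(f"expected 168 hourly rows, got {len(X)}")
    km = KMeans(n_clusters=k, n_init=restarts, max_iter=max_iter, random_state=seed)
    raw_labels = km.fit_predict(X)
    if len(np.unique(raw_labels)) < k:
        raise RuntimeError("k-means converged with an empty cluster")

    runs = _runs(raw_labels)
    onsets: dict[int, list[int]] = {c: [] for c in range(k)}
    offsets: dict[int, list[int]] = {c: [] for c in range(k)}
    for lab, start, length in runs:
        onsets[lab].append(start % 24)
        offsets[lab].append((start + length - 1) % 24)
    mode_onsets = {c: _mode_with_earliest_tie(v) for c, v in onsets.items()}

    # canonical order: anchored at the cluster with onset nearest 06:00,
    # then increasing onset hour around the clock
    def circ_dist(a: float, b: float) -> float:
        d = abs(a - b) % 24
        return min(d, 24 - d)

    anchor = min(range(k), key=lambda c: (circ_dist(mode_onsets[c], 6), mode_onsets[c]))
    order = sorted(range(k), key=lambda c: (mode_onsets[c] - mode_onsets[anchor]) % 24)
    names = list(SUBDIVISIONS) if k == 5 else [f"subdiv_{i + 1}" for i in range(k)]

    grand_raw = (
        scaler.inverse(normalized).mean() if scaler is not None else normalized.mean()
    )
    raw_table = scaler.inverse(normalized) if scaler is not None else normalized

    clusters: list[ClusterSummary] = []
    relabel = np.empty(k, dtype=int)
    for canon_idx, c in enumerate(order):
        relabel[c] = canon_idx + 1
        member = raw_labels == c
        centroid_norm = pd.Series(km.cluster_centers_[c], index=normalized.columns)
        centroid_raw = (
            scaler.inverse(centroid_norm.to_frame().T).iloc[0]
            if scaler is not None
            else centroid_norm
        )
        clusters.append(
            ClusterSummary(
                name=names[canon_idx],
                mode_onset=mode_onsets[c],
                onset_sd=_circular_sd_hours(onsets[c]),
                mode_offset=_mode_with_earliest_tie(offsets[c]),
                n_hours=int(member.sum()),
                centroid_normalized=centroid_norm,
                centroid_raw=centroid_raw,
                centroid_raw_sd=raw_table[member].std(ddof=0),
                relative_profile=centroid_raw - grand_raw,
            )
        )

    labels = pd.Series(
        relabel[raw_labels], index=pd.RangeIndex(1, 169, name="hour_of_week"), name="label"
    )
    return SubdivisionModel(
        k=k,
        labels=labels,
        clusters=clusters,
        cyclic_order_ok=_check_cyclic_order(raw_labels),
        grand_mean=grand_raw,
        seed=seed,
        restarts=restarts,
    )
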