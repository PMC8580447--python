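"""Single-track diurnal preference statistics.

Representative tracks per subdivision are chosen by tightening the
threshold rule with a 10%-of-s.d. margin and then stratifying along the
first principal component of the standardized features (five highest,
five nearest the median, five lowest). Survey ratings (1–101 sliders;
each track rated once per candidate subdivision) yield, per participant
and subdivision, a preference-difference score: the mean rating of the
subdivision's own tracks at its slot minus the mean rating of the other
subdivisions' tracks at that same slot. Scores are tested against zero
with one-sample t-tests, Bonferroni-corrected for the five comparisons.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .classifier import THRESHOLD_FEATURES
from .features import AUDIO_FEATURES
from .subdivisions import SubdivisionModel
from .synthetic import SUBDIVISIONS

logger = logging.getLogger(__name__)

#: Keep participants who rated at least this fraction of the tracks.
MIN_RATED_FRACTION = 0.66


def select_representative_candidates(
    catalog: pd.DataFrame, model: SubdivisionModel, margin: float = 0.10
) -> dict[str, pd.DataFrame]:
    """Candidate tracks beyond each subdivision's tightened threshold.

    The threshold for each of danceability, energy, liveness and
    valence is the subdivision mean shifted by ``margin`` times the
    subdivision s.d. in the direction of the subdivision's deviation
    from the grand mean; a candidate lies strictly beyond every
    tightened threshold. With ``margin=0`` this is the training-set
    qualification rule. Empty candidate sets are returned empty with a
    warning.
    """
    out: dict[str, pd.DataFrame] = {}
    for name in model.names:
        cl = model.cluster(name)
        ok = np.ones(len(catalog), dtype=bool)
        for f in THRESHOLD_FEATURES:
            mean_f = float(cl.centroid_raw[f])
            sd_f = float(cl.centroid_raw_sd[f])
            direction = 1.0 if mean_f >= float(model.grand_mean[f]) else -1.0
            threshold = mean_f + direction * margin * sd_f
            ok &= direction * (catalog[f].to_numpy(dtype=float) - threshold) > 0
        if not ok.any():
            logger.warning("no candidate tracks for subdivision %r", name)
        out[name] = catalog.loc[ok].copy()
    return out


def pca_select(candidates: pd.DataFrame, per_band: int = 5) -> pd.DataFrame:
    """Stratified shortlist along the first principal component.

    Features are standardized, PCA fitted, and the candidates ranked by
    the first component: the ``per_band`` highest, the ``per_band``
    lowest, and, among the remainder, the ``per_band`` nearest the
    median score are returned (disjoint bands, ties broken by track
    id). The selected set is invariant to the sign of the component.
    Fewer than ``3 * per_band`` candidates are returned unchanged with a
    warning.
    """
    n_needed = 3 * per_band
    if len(candidates) < n_needed:
        logger.warning(
            "only %d candidates (< %d); returning all", len(candidates), n_needed
        )
        out = candidates.copy()
        out["band"] = "all"
        return out
    feats = candidates[list(AUDIO_FEATURES)].to_numpy(dtype=float)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (feats - mu) / sd
    pca = PCA(n_components=1, random_state=0)
    pc1 = pca.fit_transform(Z)[:, 0]
    # fix the component's sign so the selection is reproducible
    lead = np.argmax(np.abs(pca.components_[0]))
    if pca.components_[0][lead] < 0:
        pc1 = -pc1

    scored = candidates.assign(pc1=pc1).sort_values(
        ["pc1", "track_id"], ascending=[False, True]
    )
    top = scored.head(per_band)
    bottom = scored.tail(per_band).sort_values(["pc1", "track_id"], ascending=[True, True])
    remaining = scored.drop(index=top.index).drop(index=bottom.index)
    median = scored["pc1"].median()
    middle = (
        remaining.assign(_dist=(remaining["pc1"] - median).abs())
        .sort_values(["_dist", "track_id"])
        .head(per_band)
        .drop(columns="_dist")
    )
    parts = [top.assign(band="top"), middle.assign(band="middle"), bottom.assign(band="bottom")]
    return pd.concat(parts).reset_index(drop=True)


def exclude_participants(
    ratings: pd.DataFrame, min_fraction: float = MIN_RATED_FRACTION
) -> pd.DataFrame:
    """Drop participants who rated no tracks or fewer than 66% of them.

    The denominator is the number of distinct tracks in the table; a
    participant counts as having rated a track if any slot rating for
    it is present.
    """
    if ratings.empty:
        return ratings.copy()
    n_tracks = ratings["track_id"].nunique()
    rated = ratings.groupby("participant_id")["track_id"].nunique()
    keep = rated[rated / n_tracks >= min_fraction].index
    dropped = rated.index.difference(keep)
    if len(dropped):
        logger.info("excluding %d participant(s) below the rating threshold", len(dropped))
    return ratings[ratings["participant_id"].isin(keep)].copy()


def preference_differences(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-participant preference-difference score for each subdivision.

    For subdivision S and participant p: the mean rating of S's own
    tracks at the S slot minus the mean rating of the other four
    subdivisions' tracks at that same slot. Missing individual ratings
    are ignored within the means; a participant with no own-subdivision
    rating at a slot gets a missing score there.

    Returns a participants x subdivisions DataFrame.
    """
    subdivisions = [s for s in SUBDIVISIONS if s in set(ratings["subdivision"])]
    participants = sorted(ratings["participant_id"].unique())
    out = pd.DataFrame(index=pd.Index(participants, name="participant_id"),
                       columns=subdivisions, dtype=float)
    for sub in subdivisions:
        slot = ratings[ratings["rated_subdivision"] == sub]
        own = slot[slot["subdivision"] == sub].groupby("participant_id")["rating"].mean()
        other = slot[slot["subdivision"] != sub].groupby("participant_id")["rating"].mean()
        out[sub] = own - other
    return out


def ttest_vs_zero(scores: pd.DataFrame, n_comparisons: int = 5) -> pd.DataFrame:
    """One-sample t-tests of the preference scores against zero.

    Per subdivision (column): mean, sample s.d. (n-1), n, t = mean /
    (s.d./sqrt(n)), df = n-1, two-sided p multiplied by
    ``n_comparisons`` and capped at 1, and the 95% confidence interval
    mean +/- t_{0.975,df} * s.d./sqrt(n). Missing scores are dropped
    per subdivision. A zero s.d. with nonzero mean yields an infinite t
    and a zero-adjacent p, with a warning.
    """
    rows = []
    for sub in scores.columns:
        x = scores[sub].dropna().to_numpy(dtype=float)
        n = len(x)
        if n < 2:
            raise ValueError(f"subdivision {sub!r} has n={n} < 2 scores")
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        df = n - 1
        if sd == 0:
            if mean != 0:
                warnings.warn(
                    f"{sub}: zero s.d. with nonzero mean; t is infinite, p ~ 0",
                    stacklevel=2,
                )
                t = float(np.inf) if mean > 0 else float(-np.inf)
                p = 0.0
            else:
                t, p = 0.0, 1.0
            half = 0.0
        else:
            se = sd / np.sqrt(n)
            t = mean / se
            p = 2.0 * float(stats.t.sf(abs(t), df))
            half = float(stats.t.ppf(0.975, df)) * se
        rows.append(
            {
                "subdivision": sub,
                "mean": mean,
                "sd": sd,
                "n": n,
                "t": t,
                "df": df,
                "p_corrected": min(1.0, p * n_comparisons),
                "ci_low": mean - half,
                "ci_high": mean + half,
            }
        )
    return pd.DataFrame(rows).set_index("subdivision")
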