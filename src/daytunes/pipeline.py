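"""End-to-end pipeline runner.

Executes simulate -> filter/aggregate -> cluster -> variability /
diversity / correlation -> trainset/train -> preference on synthetic
inputs, writing every stage's artifact to a run directory along with a
manifest (seeds, input hashes, stage summaries). Every stage reads the
previous stage's serialized output, so each is independently re-runnable
from files.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

from . import __version__, classifier, diversity, io, preference, streams, subdivisions
from .config import PipelineConfig
from .synthetic import (
    DiaryProfile,
    default_regime_profiles,
    generate_activity_diaries,
    generate_ratings,
    generate_streaming_events,
    generate_track_catalog,
    default_weekly_schedule,
)

logger = logging.getLogger(__name__)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": {},
        "hashes": {},
    }

    def record(name: str, path: Path, **info) -> None:
        manifest["stages"][name] = {"artifact": path.name, **info}
        manifest["hashes"][path.name] = io.file_sha256(path)

    # --- simulate
    profiles = default_regime_profiles()
    schedule = default_weekly_schedule()
    catalog = generate_track_catalog(config.n_tracks, profiles, seed=config.seed)
    catalog_path = out / "catalog.csv"
    io.write_catalog(catalog, catalog_path)
    record("simulate_catalog", catalog_path, n_tracks=len(catalog))

    events = generate_streaming_events(
        catalog, schedule, config.n_events, config.invalid_frac, seed=config.seed + 1
    )
    events_path = out / "events.csv"
    io.write_events(events, events_path)
    record("simulate_events", events_path, n_events=len(events))

    diaries = generate_activity_diaries(config.n_people, DiaryProfile(), seed=config.seed + 2)
    diaries_path = out / "diaries.csv"
    io.write_diaries(diaries, diaries_path)
    record("simulate_diaries", diaries_path, n_people=config.n_people)

    ratings = generate_ratings(
        config.n_participants,
        config.rating_effects,
        noise_sd=config.rating_noise_sd,
        missing_frac=config.rating_missing_frac,
        seed=config.seed + 3,
    )
    ratings_path = out / "ratings.csv"
    io.write_ratings(ratings, ratings_path)
    record("simulate_ratings", ratings_path, n_participants=config.n_participants)

    # --- filter + aggregate
    events = io.read_events(events_path)
    catalog = io.read_catalog(catalog_path)
    kept = streams.filter_events(events)
    table = streams.aggregate_hourly(kept, catalog)
    table_path = out / "hourly_table.csv"
    io.write_hourly_table(table, table_path)
    record("aggregate", table_path, n_kept=len(kept), n_total=len(events))

    # --- cluster
    table = io.read_hourly_table(table_path)
    normalized, scaler = subdivisions.zscore(table)
    curve = subdivisions.kmeans_scan(
        normalized,
        k_range=config.k_range,
        restarts=config.restarts,
        max_iter=config.scan_max_iter,
        seed=config.seed,
    )
    curve_path = out / "inertia_curve.csv"
    curve.to_csv(curve_path, index=False)
    k = subdivisions.select_k_elbow(curve)
    model = subdivisions.fit_subdivisions(
        normalized,
        k,
        restarts=config.restarts,
        max_iter=config.fit_max_iter,
        seed=config.seed,
        scaler=scaler,
    )
    model_path = out / "subdivisions.json"
    model_path.write_text(model.to_json())
    profile_path = out / "relative_profiles.csv"
    model.relative_profile_matrix().to_csv(profile_path)
    record("cluster", model_path, k=k, cyclic_order_ok=model.cyclic_order_ok)
    manifest["hashes"][curve_path.name] = io.file_sha256(curve_path)
    manifest["hashes"][profile_path.name] = io.file_sha256(profile_path)

    # --- variability / diversity / correlation
    variability = diversity.feature_variability(table)
    var_path = out / "variability.csv"
    io.write_series(variability, var_path, "feature_variability")
    grid = diversity.preprocess_diaries(io.read_diaries(diaries_path))
    div = diversity.diversity_series(grid)
    div_path = out / "diversity.csv"
    io.write_series(div, div_path, "activity_diversity")
    r, p = diversity.correlate_diversity_variability(div, variability)
    corr_path = out / "correlation.json"
    corr_path.write_text(json.dumps({"r": r, "p": p, "n": 24, "df": 22}, indent=2))
    record("correlate", corr_path, r=r, p=p)
    manifest["hashes"][var_path.name] = io.file_sha256(var_path)
    manifest["hashes"][div_path.name] = io.file_sha256(div_path)

    # --- classifier
    model = subdivisions.SubdivisionModel.from_json(model_path.read_text())
    trainset = classifier.build_training_set(io.read_catalog(catalog_path), model)
    trainset_path = out / "trainset.csv"
    trainset.drop(columns=["true_regime"], errors="ignore").to_csv(trainset_path, index=False)
    net, metrics = classifier.train_classifier(trainset, config.classifier, seed=config.seed)
    net_path = out / "network.json"
    net_path.write_text(net.to_json())
    metrics_path = out / "training_metrics.json"
    metrics_path.write_text(json.dumps(metrics, indent=2))
    record("train", net_path, **{k: v for k, v in metrics.items() if not isinstance(v, dict)})
    manifest["hashes"][trainset_path.name] = io.file_sha256(trainset_path)
    manifest["hashes"][metrics_path.name] = io.file_sha256(metrics_path)

    # --- preference
    candidates = preference.select_representative_candidates(
        io.read_catalog(catalog_path), model, margin=config.margin
    )
    shortlist = {
        name: preference.pca_select(tracks)["track_id"].tolist()
        for name, tracks in candidates.items()
        if len(tracks)
    }
    shortlist_path = out / "representative_tracks.json"
    shortlist_path.write_text(json.dumps(shortlist, indent=2))
    ratings = preference.exclude_participants(io.read_ratings(ratings_path))
    scores = preference.preference_differences(ratings)
    stats = preference.ttest_vs_zero(scores)
    stats_path = out / "preference_stats.csv"
    stats.to_csv(stats_path)
    record("preference", stats_path, n_participants=int(scores.shape[0]))
    manifest["hashes"][shortlist_path.name] = io.file_sha256(shortlist_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return manifest
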