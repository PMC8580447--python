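"""Discover the within-day listening subdivisions from synthetic streams.

Generates a track catalog and half a million streaming events on the
preset five-regime weekly schedule, filters and aggregates them per hour
of the week, picks the number of clusters with the elbow rule and fits
the subdivision model. Prints the selected k, each subdivision's modal
onset hour (with its circular spread over the week's onsets), and the
tempo/loudness columns of the relative centroid profiles — positive
values mean the subdivision sits above the weekly grand mean for that
feature.
"""

import daytunes as dt

catalog = dt.generate_track_catalog(20_000, dt.default_regime_profiles(), seed=1)
events = dt.generate_streaming_events(
    catalog, dt.default_weekly_schedule(), n_events=500_000, invalid_frac=0.1, seed=2
)
kept = dt.filter_events(events)
print(f"events kept by the validity filters: {len(kept)}/{len(events)}")

table = dt.aggregate_hourly(kept, catalog)
normalized, scaler = dt.zscore(table)

curve = dt.kmeans_scan(normalized, k_range=(2, 24), restarts=20, seed=0)
k = dt.select_k_elbow(curve)
print(f"elbow-selected number of subdivisions: k = {k}")

model = dt.fit_subdivisions(normalized, k, restarts=20, max_iter=1000, seed=0,
                            scaler=scaler)
print(f"clusters occur in one consistent cyclic order: {model.cyclic_order_ok}")
print("\nsubdivision   onset  sd(h)  offset  hours")
for c in model.clusters:
    print(f"{c.name:<13} {c.mode_onset:02d}:00  {c.onset_sd:4.2f}   {c.mode_offset:02d}:00  {c.n_hours:5d}")

profiles = model.relative_profile_matrix()
print("\nrelative centroids (vs weekly grand mean):")
print(profiles[["tempo", "loudness", "danceability", "energy"]].round(3).to_string())
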