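"""Relate musical variability to the diversity of daily activity.

Builds the 24-hour audio-feature variability series from aggregated
synthetic streams (each feature's hourly standard deviations z-scored
and averaged) and the 24-hour activity-diversity index from synthetic
one-day diaries (median descending difference of each hour's top-50
activity shares; in [-1, 0], nearer 0 = more uniform activity). Prints
both series' night/day contrast and their Pearson correlation over the
24 hours of the day — a positive r means hours with more diverse
activity also see a wider spread of music.
"""

import daytunes as dt

catalog = dt.generate_track_catalog(20_000, dt.default_regime_profiles(), seed=1)
events = dt.generate_streaming_events(
    catalog, dt.default_weekly_schedule(), n_events=500_000, invalid_frac=0.1, seed=2
)
table = dt.aggregate_hourly(dt.filter_events(events), catalog)
variability = dt.feature_variability(table)

diaries = dt.generate_activity_diaries(3000, seed=3)
grid = dt.preprocess_diaries(diaries)  # sleep + missing codes removed
diversity = dt.diversity_series(grid)

night, day = [0, 1, 2, 3, 4], [11, 12, 13, 14, 15]
print(f"feature variability  night {variability[night].mean():+.3f}   "
      f"midday {variability[day].mean():+.3f}")
print(f"activity diversity   night {diversity[night].mean():+.5f}   "
      f"midday {diversity[day].mean():+.5f}")
print("smoothed diversity (3 h window), night:",
      [round(v, 5) for v in dt.moving_average(diversity, 3)[night]])

r, p = dt.correlate_diversity_variability(diversity, variability)
print(f"\nPearson correlation over 24 h: r = {r:.2f}, p = {p:.4f} (df = 22)")
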