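# daytunes

Diurnal structure in music listening, from digital traces. Streaming
services log billions of playback events; the audio features of the
tracks people play (energy, danceability, valence, tempo, loudness, …)
drift systematically over the 24-hour day and the 7-day week. This
package implements, as a tested and reusable pipeline, the full analysis
that turns raw event logs into that picture:

1. **Hour-of-week aggregation** — playback events are filtered (track
   mostly listened to, at most one seek operation, intact timestamp) and
   each audio feature's mean and standard deviation is computed per
   unique hour of the week, h ∈ 1..168 with h = 1 at Monday 00:00.
2. **Subdivision discovery** — the 168 hourly means are z-scored per
   feature (z = (x − u)/s), clustered with k-means over k ∈ 2..24, and k
   chosen at the elbow of the inertia curve (maximum distance to the
   endpoint chord after min–max scaling). The fitted partition yields
   within-day *subdivisions* — morning, afternoon, evening, night, late
   night/early morning — each with a modal onset hour, a circular onset
   s.d., and a centroid profile relative to the weekly grand mean.
3. **Variability vs. activity diversity** — per hour of day, the mean
   z-scored feature s.d. (how wide the music being played spreads) is
   correlated with an activity-diversity index computed from time-use
   diaries: the median of the 49 consecutive differences among the
   descending proportions of the hour's top-50 activities, a value in
   [−1, 0] with 0 meaning maximally uniform activity.
4. **Playlist classification** — a feed-forward network (six audio
   features linearly remapped to (−1, 1); hidden layers 64/128/64/32,
   sigmoid; 5-way softmax) is trained on threshold-selected tracks and
   classifies a playlist by the mean of its tracks' class-probability
   vectors. Agreement with a listener's preferred subdivision is scored
   with the circular error CircErr = min(|res − pred|, 5 − |res − pred|)
   ∈ {0, 1, 2} on the five cyclically ordered classes.
5. **Single-track preference** — survey ratings (1–101 sliders, 15
   tracks, three per subdivision, each rated at every subdivision slot)
   yield per-participant preference-difference scores, tested against
   zero with one-sample t-tests and Bonferroni correction (×5).

Because the original event, diary and survey datasets are external, the
package ships a first-class synthetic-data module that generates all
inputs with the statistical structure the analysis assumes — per-hour
mixtures of regime-specific feature distributions with weekday/weekend
schedule differences, filter-failing events at a controlled rate,
diaries with per-hour activity concentration, ratings with planted
effects — plus ground-truth labels, so every stage has a recovery
oracle. See `docs/methods.md` for the model and all numerical choices.

## A worked example

`python examples/01_discover_subdivisions.py` simulates 500 000 events
on the preset five-regime week, aggregates them and fits the model:

```
events kept by the validity filters: 449698/500000
elbow-selected number of subdivisions: k = 5
clusters occur in one consistent cyclic order: True

subdivision   onset  sd(h)  offset  hours
morning       06:00  0.00   11:00     42
afternoon     12:00  0.00   19:00     56
evening       20:00  0.00   22:00     30
night         23:00  2.07   03:00     28
late_night    04:00  0.45   05:00     12
```

The elbow rule recovers the five planted regimes; onsets land exactly on
the preset schedule (the night onset's 2.07 h circular s.d. reflects the
planted weekend shift, where extended Friday/Saturday evenings push the
night onset to 03:00–04:00). The relative centroids show the planted
structure: mornings louder and slower than the weekly average, evenings
fastest and most danceable, nights quietest and slowest.

`python examples/04_track_preference.py` runs the survey arm at n = 176
with planted effects (+4, −4, 0, −5, +11 rating points):

```
subdivision    planted    mean     sd      t     p(corr)   95% CI
morning          +4.0   +3.64  13.68  +3.53    0.003  [+1.61, +5.68]
afternoon        -4.0   -2.98  13.74  -2.87    0.023  [-5.02, -0.93]
evening          +0.0   -0.07  13.97  -0.07    1.000  [-2.16, +2.01]
night            -5.0   -4.95  13.13  -5.00    0.000  [-6.90, -2.99]
late_night      +11.0  +11.23  13.60 +10.95    0.000  [+9.21, +13.25]
```

Each planted effect falls inside its recovered 95% confidence interval;
the null (evening) subdivision is correctly non-significant after
Bonferroni correction.

The other examples: `02_activity_diversity.py` (variability/diversity
correlation over the 24 hours of the day) and `03_playlist_classifier.py`
(training the network and classifying a playlist, a couple of minutes).

## Command line

The same stages are available as subcommands for file-based runs:

```sh
daytunes simulate-events --n-tracks 20000 --n-events 500000 \
    --catalog catalog.csv --out events.csv
daytunes aggregate --events events.csv --catalog catalog.csv --out hourly.csv
daytunes cluster --table hourly.csv --out model.json
daytunes run-all --out run/        # every stage, with a hashed manifest
```

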