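# Methods

This note documents the models, conventions and numerical choices
behind each stage of the pipeline, what the synthetic-data generators
emulate (and do not), and the design decisions taken where more than
one reading was defensible.

## Event filtering and hourly aggregation

A playback event is analysable when the listener heard most of the
track (`listened_most`), performed at most one seek-forward or
seek-backward operation (`n_seek_ops <= 1`), and the event's weekday and
hour are present, in range, and flagged valid. Malformed rows are
rejected per-row with a logged reason rather than aborting the run.

Kept events are binned by hour of the week, h = 24·weekday + hour + 1,
so h = 1 is Monday 00:00 and h = 168 is Sunday 23:00. Aggregation is
event-weighted: a track streamed twice contributes twice, because the
unit of analysis is the playback event, not the unique track. Per hour
and feature we report the mean and the **population** standard
deviation (divide by n). The population form is chosen for consistency
with the z-scoring convention below; at the event counts involved the
two forms are numerically indistinguishable, and the choice is
configurable where it matters (tests pin the population form).

Hours with zero events are marked missing and rejected by the
clustering stage, which requires a complete 168-row table; partial
weeks are treated as a data problem, not silently interpolated.

## Audio features

Fifteen per-track scalar features are carried end to end: energy,
danceability, acousticness, mean dynamic range (dB), beat strength,
liveness, organism, mechanism, valence, bounciness, flatness, loudness
(dBFS), speechiness, instrumentalness and tempo (BPM). Eleven are
bounded in [0, 1]; dynamic range is non-negative; tempo is positive;
loudness is nominally within [−60, 0] dBFS but positive values occur in
real catalogs, so only the lower bound is enforced on ingest.

## Subdivision discovery

Each feature's 168 hourly means are standardized, z = (x − u)/s with u
and s the mean and population s.d. across the 168 hours; a constant
column is an error naming the feature (a degenerate week cannot be
clustered meaningfully). k-means (k-means++ initialization, best of 20
restarts, fixed seed) is scanned over k ∈ 2..24 at 100 maximum
iterations per k; the final model is refitted at the selected k with
1000 maximum iterations.

The number of clusters is selected by an automated elbow rule: with
both axes min–max scaled to [0, 1], choose the k whose (k, inertia)
point lies farthest from the chord joining the curve's endpoints.
Endpoints are ineligible (their distance is identically zero), and ties
within floating-point tolerance resolve to the smallest k, so a
featureless straight-line curve yields the smallest interior k. On
convex curves with a visible knee this rule matches visual selection
while being reproducible.

Temporal structure is summarised from the fitted labels on the circular
168-hour week. A *run* is a maximal circular stretch of one label (runs
may cross midnight). A cluster's onsets are the hours of day at which
its runs begin; the modal onset breaks ties toward the earlier hour,
and its spread is reported as a **circular** standard deviation in
hours, since onsets near midnight wrap. The offset is the last hour of
day of the cluster's runs (mode), equivalently the hour before the next
cluster's onset. The week is flagged as *cyclically ordered* when the
sequence of runs around the whole week is generated by a single cycle
through all k labels — every cluster is always followed by the same
next cluster. This week-level formulation is deliberately used instead
of a per-calendar-day rotation check, which falsely fails when a
weekend evening run crosses midnight and the same label appears twice
within one calendar day.

Clusters are canonicalized by modal onset, anchored at the cluster
whose onset is nearest 06:00 and proceeding in onset order around the
clock; with k = 5 the canonical names morning, afternoon, evening,
night, late night/early morning apply. All reported quantities are
invariant to the arbitrary k-means label permutation.

Centroids are reported on three scales: normalized (the k-means
centroid), raw (inverse z-transform), and *relative* — the raw centroid
minus the grand mean profile, the per-feature mean over the 168 hourly
means, unweighted by event counts. The size-weighted relative profiles
sum to zero across clusters by construction. Each cluster also carries
a per-feature s.d. of its member hours' raw means; this is the spread
statistic used by the representative-track thresholds below. (With
track-level data one could instead use the s.d. over member tracks; the
hourly-mean form is what the generic event/catalog schema supports at
this stage, and only the relative magnitudes enter the selection
rules.)

## Feature variability and activity diversity

**Variability.** Per feature, the 168 hourly standard deviations are
z-scored across hours — "normalized" is read as the same
standardization used everywhere else in the pipeline, which makes
features on different scales (BPM, dB, unit intervals) commensurable —
then averaged over the seven days per hour of day and over the 15
features, giving a 24-value series.

**Diaries.** Minute-resolution activity reports (one diary day per
person) are rounded to full hours — floor(start_minute/60), with
nearest-hour available as an option — and forward-filled so every hour
from the first report onward carries a code; when several reports fall
in one hour the last one defines that hour (it is the state carried
forward). Sleeping codes {010101, 010199, 010102} and missing-data
codes (≥ 500101) are then blanked, *after* filling, so an hour whose
filled state was sleep contributes nothing to that hour's counts.
Persons left with no valid hour are dropped with a log entry.

**Index.** For each hour of day, activity proportions are computed over
activity instances (person-hours), ranked descending, truncated or
zero-padded to the top 50, and differenced consecutively (next minus
current, each ≤ 0); the index is the median of the 49 differences. It
lies in [−1, 0], with values nearer 0 indicating more uniform (diverse)
activity. Padding with zero-proportion entries keeps the statistic
defined when fewer than 50 activities occur. The definition has an
inherent quirk, implemented as stated: an extremely concentrated hour
whose ranked tail is all zeros also yields a median of 0, so the index
is informative only in the regime where the top-50 ranks carry mass —
which large diary corpora occupy.

**Correlation.** The two 24-value series are compared with a Pearson
correlation; the two-sided p comes from the t transform with 22 degrees
of freedom. The correlation uses the raw series; a circular centered
moving average (default window 3 h, odd windows only) is provided for
presentation-style smoothing but deliberately kept out of the test
statistic.

## Playlist classifier

**Training set.** For each subdivision, thresholds are placed at the
subdivision's mean for danceability, energy, liveness and valence —
speechiness, acousticness and instrumentalness are excluded for their
highly non-normal distributions. A track qualifies when each of the
four features lies strictly beyond the subdivision mean in the
direction of that subdivision's deviation from the weekly grand mean
(above when the subdivision sits above the grand mean, below
otherwise); a track exactly at a mean does not qualify. Tracks
qualifying for several subdivisions are assigned to the *nearest* one
by mean standardized distance to the subdivision's threshold-feature
means. A margin-maximizing assignment was considered and rejected:
whenever two subdivisions share directions on all four features their
qualification sets nest, and the laxer set always offers the larger
margin, so the stricter subdivision is left empty — precisely the
degenerate outcome the builder treats as an error. Nearest-centroid
assignment keeps nested qualifiers with the more specific class. Class
imbalance in the result is expected and handled by balanced class
weights, w_c = N/(K·n_c).

**Remapping.** The six network inputs (danceability, energy, loudness,
liveness, valence, tempo) are linearly remapped to (−1, 1) rather than
standardized, so a deployed model needs no scaler state: loudness
clamps to [−60, 12] dB and tempo to [40, 220] BPM before the affine
map; unit-interval features map as x ↦ 2x − 1. The map is monotone and
sends the clamp bounds exactly to ±1.

**Architecture and training.** Four fully connected sigmoid hidden
layers of 64, 128, 64 and 32 units feed a 5-way softmax. Dropout of
0.30 is applied between the hidden layers (after the first three); an
L1 penalty of 0.01 is applied to the last three hidden layers as an
**activity** regularizer, 0.01 · mean over the batch of Σ|activation|,
added to the loss. The activity reading is a deliberate choice: with
Adam at the canonical learning rate of 1e-4, an L1 penalty on the
*weights* contributes a constant 0.01-magnitude gradient that dominates
the data gradient (~1e-3 at these layer widths), drives the inner
layers to ~1e-5 within a few hundred steps and leaves the network
permanently at chance — we verified this empirically, and it
contradicts the accuracy this architecture demonstrably reaches. The
per-sample-mean activity penalty is the standard reading under which
the architecture trains; it is self-limiting because the sigmoid's
derivative vanishes as activations saturate toward zero. Training uses
class-weighted categorical cross-entropy, batch size 32, shuffling
between epochs, an 80/20 development/holdout split and a further 80/20
training/validation split (both stratified), and early stopping once
validation accuracy has not improved for 30 epochs, restoring the best
weights; the epoch cap defaults to 200, past the observed convergence
point. The network is implemented directly on numpy with manual
backpropagation and Glorot-uniform initialization; given a seed and
single-threaded execution, training is bit-reproducible, which the
tests rely on.

Training-set scale matters at this learning rate: with ~33 000 training
tracks (the default 500 000-track catalog yields this after
thresholding) an epoch is ~840 batches and the patience window spans
~25 000 updates; at a tenth of that scale the early stop fires before
learning starts. The defaults encode the former regime.

**Prediction and agreement.** A playlist's tracks are classified
separately and the class-probability vectors averaged; the predicted
subdivision is the argmax of the mean, ties breaking toward the earlier
subdivision in canonical order. Listener agreement uses the circular
error on the five cyclically ordered classes, CircErr(res, pred) =
min(|res − pred|, 5 − |res − pred|) ∈ {0, 1, 2} — the shortest step
distance around the daily cycle, a metric on Z₅ with maximum 2.
Agreement reports give the fraction of zero-error responses and the
mean error, per predicted class and overall.

## Single-track preference

Representative candidates per subdivision tighten the training-set rule
by a margin of 10% of the subdivision's s.d.: the threshold becomes
mean ± 0.10·s.d., shifted in the direction of the subdivision's
deviation from the grand mean, selecting tracks from the extremes of
each distribution. Candidates are then stratified along the first
principal component of the standardized features: the five highest, the
five lowest, and — among the remainder — the five nearest the median
score ("around the middle" is read as nearest-median rather than an
index-based middle block; the bands are disjoint, ties break on track
id, and the component's sign is fixed by its largest loading so the
selection is reproducible and invariant to sign flips).

Ratings are 1–101 slider values; each of 15 tracks (three per
subdivision) is rated once per candidate subdivision. Participants who
rated no tracks or fewer than 66% of them are excluded. The
preference-difference score for participant p and subdivision S is the
mean rating of S's own tracks *at the S slot* minus the mean rating of
the other four subdivisions' tracks at that same slot — the matched-
slot reading of "do people prefer morning tracks in the morning".
Missing individual ratings are ignored within means rather than
imputed; a participant with no own-subdivision rating at a slot gets a
missing score there. Scores are tested against zero per subdivision:
t = mean/(s/√n) with the sample s.d. (n − 1), df = n − 1, two-sided p
multiplied by 5 (Bonferroni) and capped at 1.0 — a printed 0.999 is
treated as a display convention for the cap — and a 95% CI of
mean ± t₀.₉₇₅,df · s/√n. A zero s.d. with nonzero mean yields an
infinite t and a zero-adjacent p with a warning.

## The synthetic-data generators

The generators define the study conditions for every test; their
defaults are fixed once and shared by the test suite and examples.

**Regimes.** Five regime profiles give each audio feature a truncated
normal distribution (truncation at the feature's documented range).
The within-regime distribution family is a modelling choice: it is
not observable from summary structure; truncated normals are the
simplest family reproducing the mean-shift picture. Means sit at a
common baseline (energy 0.64, danceability 0.62, valence 0.50, tempo
122.5 BPM, loudness −8 dBFS, …) with regime deltas following the
qualitative centroid structure: mornings louder (+1.6 dB), more
positive (+0.07 valence) and more energetic but slower (−3 BPM);
afternoons faster (+2 BPM); evenings fastest (+3.5 BPM) with peak beat
strength, danceability and bounciness; nights quietest (−3 dB) and
slowest (−4.5 BPM) with reduced energy and valence; late night/early
morning resembling night with energy and valence partly recovered
(valence placed slightly above the weekly mean so its threshold
signature is distinct from the night's). Within-regime s.d.s are wide
(0.18 on unit features, 28 BPM, 4 dB), reflecting that diurnal
structure lives in small mean shifts on top of broadly overlapping
distributions; the night (×1.35) and late-night (×1.6) spreads are
inflated so the variability series peaks in the small hours. A
`well_separated_profiles` variant (deltas ×4, s.d.s ×0.45) provides the
near-separable regime used by classifier contract checks. A
`separation` parameter scales all deltas for sensitivity studies.

**Schedule.** The preset week assigns each hour one regime (a
degenerate mixture; the schedule type supports true mixtures): weekday
onsets late-night 04:00, morning 06:00, afternoon 12:00, evening
20:00, night 23:00; Friday and Saturday evenings extend past midnight,
pushing the night onset to 03:00/04:00 and the weekend late-night
onset to 05:00. These onset hours are illustrative of commonly
observed diurnal listening structure, not measurements. Events are
uniform over the 168 hours; an `invalid_frac` of events fails exactly
one validity filter (not listened, ≥2 seeks, or corrupt timestamp),
chosen uniformly, with the planted validity recorded in ground truth.

**Diaries.** One day per person. Each person reports at minute 0 and
then starts a new activity in any hour with probability 0.7 at a
uniform minute, exercising rounding and forward-fill. Hourly activity
distributions rank 59 codes (3 sleep, 54 regular, 2 missing) with
weight exp(−c·rank); the concentration c defaults to 0.02 in the small
hours (22:00–05:00) and 0.06 during the day, planting higher night-time
diversity, and sleep codes rank first during sleep hours so the sleep
filter has real work. Around 3000 persons are needed for the top-50
ranks to carry mass; below that the index degenerates toward 0 (see the
quirk above).

**Ratings.** Rating = 51 + participant baseline (s.d. 8) + planted
effect (added only when a track is rated at its own subdivision's slot)
+ noise (s.d. 20), clipped to [1, 101]; whole tracks go unrated with
probability `missing_frac`. Baselines cancel exactly in the difference
scores; clipping attenuates planted effects by well under the CI width
at the default noise level.

**What the generators do not emulate** — and hence what passing tests
do not establish about real data: session structure and sequential
listening behaviour; non-uniform listening volume over the day;
demographic, geographic or individual-level heterogeneity; real
activity lexicons and multi-day diaries; correlated audio features
within regimes (features are sampled independently given the regime);
track popularity (tracks are streamed uniformly within a regime); and
any relationship between the survey tracks and the streaming catalog.
Recovery results show the pipeline is correct and well-calibrated under
its own assumptions, not that those assumptions hold in the wild.

## Problem sizes and determinism

The test suite runs the full recovery analysis at ~2 × 10⁶ events over
a 20 000-track catalog (clustering, onsets, adjusted Rand ≥ 0.9), the
classifier contract at a 500 000-track catalog (~36 000 training
tracks), and confidence-interval coverage over 200 replicates of the
n = 176 survey — sizes chosen so each check is decisive at desk scale.
All randomness flows from explicit integer seeds through numpy
generators; identical seeds give byte-identical generator output and
bit-identical training, and the pipeline manifest records SHA-256
hashes of every artifact so a run can be verified end to end.

## Known limitations

- The elbow rule assumes a convex inertia curve with one knee; curves
  with multiple comparable knees resolve to the smallest k within
  tolerance, which may not match visual judgment on pathological data.
- The onset s.d. is circular; for clusters with very few runs (e.g. a
  regime appearing once) it is 0 by construction and uninformative.
- The activity-diversity index's degenerate-0 behaviour at extreme
  concentration is inherent to its definition and intentionally not
  corrected.
- The classifier's determinism contract holds for single-threaded
  execution; BLAS-level nondeterminism in exotic configurations is out
  of scope.
- Real-data adapters (streaming-service exports, survey platforms,
  government diary formats) are deliberately out of scope; the package
  reads the generic CSV/NDJSON schemas documented in `daytunes.io`.
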