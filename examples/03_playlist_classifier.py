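"""Train the subdivision network and classify a playlist.

Builds a labelled training set by thresholding a large synthetic catalog
against the fitted subdivision model, trains the feed-forward classifier
(six remapped audio features -> 64/128/64/32 sigmoid hidden layers ->
5-way softmax), and classifies a small playlist of night-regime tracks
by averaging the per-track class probabilities. The circular error
scores a listener's response against the prediction on the 5-class
daily cycle (0 = agreement, 2 = opposite end).

Training at the canonical learning rate takes a couple of minutes.
"""

import daytunes as dt
from daytunes.classifier import CLASSIFIER_FEATURES

catalog = dt.generate_track_catalog(500_000, dt.well_separated_profiles(), seed=1)
events = dt.generate_streaming_events(
    catalog, dt.default_weekly_schedule(), n_events=300_000, invalid_frac=0.0, seed=2
)
table = dt.aggregate_hourly(events, catalog)
normalized, scaler = dt.zscore(table)
model = dt.fit_subdivisions(normalized, 5, restarts=20, seed=0, scaler=scaler)

trainset = dt.build_training_set(catalog, model)
print("training-set class counts:", trainset["label"].value_counts().to_dict())

net, metrics = dt.train_classifier(trainset, seed=0)
print(f"holdout accuracy: {metrics['holdout_accuracy']:.4f} "
      f"(loss {metrics['holdout_loss']:.4f}, {metrics['epochs']} epochs)")

# a playlist of ten tracks drawn from the night regime
playlist = catalog[catalog["true_regime"] == "night"].head(10)
pred = dt.classify_playlist(net, playlist[list(CLASSIFIER_FEATURES)])
print("\nmean class probabilities:")
for name, prob in zip(pred.classes, pred.mean_probabilities):
    print(f"  {name:<12} {prob:.3f}")
print(f"predicted subdivision: {pred.predicted}")

classes = list(pred.classes)
response = "late_night"  # a listener who prefers this playlist later
err = dt.circular_error(classes.index(response) + 1, classes.index(pred.predicted) + 1)
print(f"circular error vs a '{response}' response: {err}")
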