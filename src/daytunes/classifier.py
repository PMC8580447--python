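"""Subdivision classification of tracks and playlists.

A training set is built by thresholding tracks against each
subdivision's mean for danceability, energy, liveness and valence (above
the mean when the subdivision sits above the weekly grand mean, below
otherwise; speechiness, acousticness and instrumentalness are ignored
for their highly non-normal distributions). Six features (danceability,
energy, loudness, liveness, valence, tempo) are linearly remapped to
(-1, 1) and fed to a small feed-forward network — four sigmoid hidden
layers of 64, 128, 64 and 32 units, 30% dropout between hidden layers,
an L1 penalty of 0.01 on the last three hidden layers, and a 5-way
softmax output — trained with Adam at learning rate 1e-4 on a
class-weighted categorical cross-entropy, batch size 32, with early
stopping once validation accuracy has not improved for 30 epochs.

A playlist is classified by averaging its tracks' class-probability
vectors; agreement between predictions and listener responses is scored
with the circular error, the shortest step distance between two of the
five cyclically ordered subdivisions (0..2).

The network is implemented directly on numpy (manual backpropagation);
training is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .subdivisions import SubdivisionModel
from .synthetic import SUBDIVISIONS

#: Features entering the network, in input order.
CLASSIFIER_FEATURES: tuple[str, ...] = (
    "danceability",
    "energy",
    "loudness",
    "liveness",
    "valence",
    "tempo",
)

#: Features used for threshold qualification when building the training set.
THRESHOLD_FEATURES: tuple[str, ...] = ("danceability", "energy", "liveness", "valence")

#: Clamp bounds for the (-1, 1) remapping of the unbounded features.
REMAP_BOUNDS: dict[str, tuple[float, float]] = {
    "loudness": (-60.0, 12.0),
    "tempo": (40.0, 220.0),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters of the subdivision network (defaults are canonical)."""

    hidden: tuple[int, ...] = (64, 128, 64, 32)
    dropout: float = 0.30
    l1: float = 0.01  # applied to the last three hidden layers
    learning_rate: float = 1e-4
    batch_size: int = 32
    patience: int = 30
    val_split: float = 0.20
    holdout_split: float = 0.20
    max_epochs: int = 200


def remap_features(values, feature_names: tuple[str, ...] = CLASSIFIER_FEATURES) -> np.ndarray:
    """Linearly remap features to (-1, 1).

    Loudness clamps to [-60, 12] dB and tempo to [40, 220] BPM before
    the affine map; the unit-interval features map as x -> 2x - 1.
    Accepts a mapping/Series (returns a 1-D vector) or a DataFrame
    (returns an (n, len(feature_names)) array).
    """
    if isinstance(values, pd.DataFrame):
        cols = []
        for f in feature_names:
            cols.append(_remap_column(values[f].to_numpy(dtype=float), f))
        return np.column_stack(cols)
    out = np.empty(len(feature_names))
    for i, f in enumerate(feature_names):
        out[i] = _remap_column(np.asarray([float(values[f])]), f)[0]
    return out


def _remap_column(x: np.ndarray, feature: str) -> np.ndarray:
    if feature in REMAP_BOUNDS:
        lo, hi = REMAP_BOUNDS[feature]
        x = np.clip(x, lo, hi)
        return 2.0 * (x - lo) / (hi - lo) - 1.0
    return 2.0 * x - 1.0


def build_training_set(catalog: pd.DataFrame, model: SubdivisionModel) -> pd.DataFrame:
    """Label catalog tracks by threshold qualification against the model.

    A track qualifies for a subdivision when, for each of danceability,
    energy, liveness and valence, its value lies strictly beyond the
    subdivision's mean in the direction of that subdivision's deviation
    from the weekly grand mean. Tracks qualifying for several
    subdivisions go to the nearest one: the smallest mean standardized
    distance to the subdivision's threshold-feature means. (When two
    subdivisions share directions on all four features their
    qualification sets nest, and any margin-maximizing rule would strip
    the stricter subdivision bare; the nearest-centroid rule keeps
    nested qualifiers with the more specific class.) Returns the
    qualifying rows of ``catalog`` with a ``label`` column; a
    subdivision attracting no track is an error.
    """
    names = model.names
    n = len(catalog)
    distances = np.full((n, len(names)), np.inf)
    for j, name in enumerate(names):
        cl = model.cluster(name)
        ok = np.ones(n, dtype=bool)
        feat_dist = np.zeros((n, len(THRESHOLD_FEATURES)))
        for fi, f in enumerate(THRESHOLD_FEATURES):
            mean_f = float(cl.centroid_raw[f])
            sd_f = float(cl.centroid_raw_sd[f])
            direction = 1.0 if mean_f >= float(model.grand_mean[f]) else -1.0
            x = catalog[f].to_numpy(dtype=float)
            signed = direction * (x - mean_f)
            ok &= signed > 0  # strict: a track exactly at the mean does not qualify
            feat_dist[:, fi] = np.abs(x - mean_f) / sd_f if sd_f > 0 else np.abs(x - mean_f)
        distances[ok, j] = feat_dist[ok].mean(axis=1)

    qualified = np.isfinite(distances).any(axis=1)
    assigned = distances.argmin(axis=1)
    out = catalog.loc[qualified].copy()
    out["label"] = [names[j] for j in assigned[qualified]]
    counts = out["label"].value_counts()
    empty = [nm for nm in names if nm not in counts.index]
    if empty:
        raise ValueError(f"no qualifying tracks for subdivision(s): {empty}")
    return out


def class_weights(counts: dict[str, int]) -> dict[str, float]:
    """Balanced class weights w_c = N / (K * n_c)."""
    if any(c <= 0 for c in counts.values()):
        raise ValueError("all class counts must be > 0")
    total = sum(counts.values())
    k = len(counts)
    return {c: total / (k * n) for c, n in counts.items()}


# ---------------------------------------------------------------------------
# The network


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SubdivisionNetwork:
    """Feed-forward subdivision classifier (numpy, manual backprop)."""

    def __init__(self, classes: list[str], spec: ClassifierSpec, seed: int = 0):
        self.classes = list(classes)
        self.spec = spec
        sizes = [len(CLASSIFIER_FEATURES), *spec.hidden, len(classes)]
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._rng = rng

    # hidden layers whose activations carry the L1 penalty: the last three.
    # The penalty is an activity regularizer — l1 * sum|activation| added
    # to the batch loss. Penalizing the weights instead would be fatal
    # here: a constant 0.01 weight-gradient outweighs the data gradient
    # at learning rate 1e-4 and drives the inner layers to zero before
    # any learning happens; the activity form is self-limiting because
    # the sigmoid's derivative vanishes as activations saturate low.
    def _l1_layers(self) -> list[int]:
        n_hidden = len(self.spec.hidden)
        return list(range(max(0, n_hidden - 3), n_hidden))

    def _forward(
        self, X: np.ndarray, train: bool = False
    ) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray | None]]:
        acts = [X]
        masks: list[np.ndarray | None] = []
        h = X
        n_hidden = len(self.spec.hidden)
        for li in range(n_hidden):
            h = _sigmoid(h @ self.weights[li] + self.biases[li])
            # dropout between hidden layers (after all but the last hidden layer)
            if train and self.spec.dropout > 0 and li < n_hidden - 1:
                mask = (self._rng.random(h.shape) >= self.spec.dropout) / (
                    1.0 - self.spec.dropout
                )
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
        probs = _softmax(h @ self.weights[-1] + self.biases[-1])
        acts.append(probs)
        return probs, acts, masks

    def predict_proba(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Class probabilities for raw (un-remapped) feature rows."""
        X = (
            remap_features(features)
            if isinstance(features, pd.DataFrame)
            else np.asarray(features, dtype=float)
        )
        probs, _, _ = self._forward(X, train=False)
        return probs

    def _train_step(
        self, X: np.ndarray, y: np.ndarray, sample_w: np.ndarray, adam_state, t: int
    ) -> float:
        spec = self.spec
        probs, acts, masks = self._forward(X, train=True)
        n = len(X)
        w = sample_w / sample_w.sum() * n  # keep loss scale comparable
        loss = float(-(w * np.log(probs[np.arange(n), y] + 1e-12)).mean())

        grads_W = [np.zeros_like(W) for W in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]

        onehot = np.zeros_like(probs)
        onehot[np.arange(n), y] = 1.0
        delta = (probs - onehot) * w[:, None] / n
        grads_W[-1] = acts[-2].T @ delta
        grads_b[-1] = delta.sum(axis=0)

        n_hidden = len(spec.hidden)
        l1_layers = set(self._l1_layers())
        for li in range(n_hidden - 1, -1, -1):
            delta = delta @ self.weights[li + 1].T
            if masks[li] is not None:
                delta = delta * masks[li]
            a = acts[li + 1]
            # a already includes dropout scaling; derivative uses pre-dropout
            # sigmoid output, recovered by dividing the mask back out
            pre = a if masks[li] is None else a / np.where(masks[li] == 0, 1.0, masks[li])
            if li in l1_layers and spec.l1 > 0:
                # activity penalty l1 * mean-over-batch of sum|a| per sample;
                # sigmoid outputs are positive so |a| = a
                loss += spec.l1 * float(pre.sum()) / n
                delta = delta + spec.l1 / n
            delta = delta * pre * (1.0 - pre)
            grads_W[li] = acts[li].T @ delta
            grads_b[li] = delta.sum(axis=0)

        # Adam update
        mW, vW, mb, vb = adam_state
        b1, b2, eps = 0.9, 0.999, 1e-7
        lr = spec.learning_rate
        for li in range(len(self.weights)):
            mW[li] = b1 * mW[li] + (1 - b1) * grads_W[li]
            vW[li] = b2 * vW[li] + (1 - b2) * grads_W[li] ** 2
            mb[li] = b1 * mb[li] + (1 - b1) * grads_b[li]
            vb[li] = b2 * vb[li] + (1 - b2) * grads_b[li] ** 2
            mW_hat = mW[li] / (1 - b1**t)
            vW_hat = vW[li] / (1 - b2**t)
            mb_hat = mb[li] / (1 - b1**t)
            vb_hat = vb[li] / (1 - b2**t)
            self.weights[li] -= lr * mW_hat / (np.sqrt(vW_hat) + eps)
            self.biases[li] -= lr * mb_hat / (np.sqrt(vb_hat) + eps)
        return loss

    def get_state(self) -> list[np.ndarray]:
        return [W.copy() for W in self.weights] + [b.copy() for b in self.biases]

    def set_state(self, state: list[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = [s.copy() for s in state[:n]]
        self.biases = [s.copy() for s in state[n:]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": self.classes,
                "features": list(CLASSIFIER_FEATURES),
                "hidden": list(self.spec.hidden),
                "remap_bounds": REMAP_BOUNDS,
                "weights": [W.tolist() for W in self.weights],
                "biases": [b.tolist() for b in self.biases],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SubdivisionNetwork":
        d = json.loads(text)
        net = cls(d["classes"], ClassifierSpec(hidden=tuple(d["hidden"])))
        net.weights = [np.asarray(W) for W in d["weights"]]
        net.biases = [np.asarray(b) for b in d["biases"]]
        return net


def train_classifier(
    trainset: pd.DataFrame,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
) -> tuple[SubdivisionNetwork, dict]:
    """Train the subdivision network on a labelled track set.

    ``trainset`` needs the six classifier feature columns and a
    ``label`` column covering all five subdivisions. The data is split
    80/20 into development and holdout sets (stratified), the
    development set again 80/20 into training and validation; training
    uses class-weighted cross-entropy with shuffling between epochs and
    stops once validation accuracy has not improved for ``patience``
    epochs, restoring the best weights. Returns the network and a
    metrics dict (holdout accuracy overall and per class, holdout
    loss, epochs run).
    """
    spec = spec or ClassifierSpec()
    classes = [s for s in SUBDIVISIONS if s in set(trainset["label"])]
    extra = sorted(set(trainset["label"]) - set(SUBDIVISIONS))
    classes += extra
    if len(classes) < 2:
        raise ValueError("trainset must contain at least two classes")

    X = remap_features(trainset[list(CLASSIFIER_FEATURES)])
    y = np.array([classes.index(lab) for lab in trainset["label"]])

    X_dev, X_hold, y_dev, y_hold = train_test_split(
        X, y, test_size=spec.holdout_split, random_state=seed, stratify=y
    )
    X_tr, X_val, y_tr, y_val = train_test_split(
        X_dev, y_dev, test_size=spec.val_split, random_state=seed, stratify=y_dev
    )

    counts = {c: int((y_tr == i).sum()) for i, c in enumerate(classes)}
    weights = class_weights(counts)
    w_tr = np.array([weights[classes[c]] for c in y_tr])

    net = SubdivisionNetwork(classes, spec, seed=seed)
    adam_state = (
        [np.zeros_like(W) for W in net.weights],
        [np.zeros_like(W) for W in net.weights],
        [np.zeros_like(b) for b in net.biases],
        [np.zeros_like(b) for b in net.biases],
    )
    shuffle_rng = np.random.default_rng(seed + 1)
    best_acc, best_state, best_epoch = -1.0, net.get_state(), 0
    t = 0
    epoch = 0
    for epoch in range(1, spec.max_epochs + 1):
        order = shuffle_rng.permutation(len(X_tr))
        for start in range(0, len(X_tr), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            t += 1
            net._train_step(X_tr[idx], y_tr[idx], w_tr[idx], adam_state, t)
        val_acc = float((net.predict_proba(X_val).argmax(axis=1) == y_val).mean())
        if val_acc > best_acc:
            best_acc, best_state, best_epoch = val_acc, net.get_state(), epoch
        elif epoch - best_epoch >= spec.patience:
            break
    net.set_state(best_state)

    hold_probs = net.predict_proba(X_hold)
    hold_pred = hold_probs.argmax(axis=1)
    per_class = {
        c: float((hold_pred[y_hold == i] == i).mean()) if (y_hold == i).any() else float("nan")
        for i, c in enumerate(classes)
    }
    metrics = {
        "holdout_accuracy": float((hold_pred == y_hold).mean()),
        "holdout_loss": float(
            -np.log(hold_probs[np.arange(len(y_hold)), y_hold] + 1e-12).mean()
        ),
        "per_class_accuracy": per_class,
        "validation_accuracy": best_acc,
        "epochs": epoch,
        "class_counts": counts,
    }
    return net, metrics


# ---------------------------------------------------------------------------
# Playlist prediction and agreement


@dataclass(frozen=True)
class PlaylistPrediction:
    classes: tuple[str, ...]
    track_probabilities: np.ndarray  # (n_tracks, n_classes)
    mean_probabilities: np.ndarray  # (n_classes,)
    predicted: str = field(init=False)

    def __post_init__(self) -> None:
        sums = self.track_probabilities.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("track probability rows must sum to 1")
        # argmax takes the first maximum: ties break toward the earlier
        # subdivision in canonical order
        object.__setattr__(
            self, "predicted", self.classes[int(self.mean_probabilities.argmax())]
        )


def classify_playlist(
    net: SubdivisionNetwork, tracks: pd.DataFrame
) -> PlaylistPrediction:
    """Classify a playlist by averaging per-track class probabilities."""
    if len(tracks) == 0:
        raise ValueError("cannot classify an empty playlist")
    probs = net.predict_proba(tracks[list(CLASSIFIER_FEATURES)])
    return PlaylistPrediction(
        classes=tuple(net.classes),
        track_probabilities=probs,
        mean_probabilities=probs.mean(axis=0),
    )


def circular_error(res: int, pred: int, n_classes: int = 5) -> int:
    """Shortest step distance between two cyclically ordered classes.

    Classes are numbered 1..n_classes around the daily cycle; the error
    is min(|res - pred|, n - |res - pred|), at most floor(n/2) (2 for
    the five subdivisions) and 0 iff the classes agree.
    """
    for v in (res, pred):
        if not (isinstance(v, (int, np.integer)) and 1 <= v <= n_classes):
            raise ValueError(f"class must be an integer in 1..{n_classes}, got {v!r}")
    d = abs(int(res) - int(pred))
    return min(d, n_classes - d)


def agreement_report(responses: list[tuple[int, int]]) -> pd.DataFrame:
    """Agreement and mean circular error per predicted class and overall.

    ``responses`` holds (pred, res) class pairs in 1..5. Agreement is
    the fraction of pairs with circular error 0, in percent.
    """
    if not responses:
        return pd.DataFrame(columns=["n", "agreement_pct", "mean_error"])
    rows = []
    errors = [(pred, circular_error(res, pred)) for pred, res in responses]
    frame = pd.DataFrame(errors, columns=["pred", "error"])
    for pred, grp in frame.groupby("pred"):
        rows.append(
            {
                "predicted": SUBDIVISIONS[pred - 1] if 1 <= pred <= 5 else str(pred),
                "n": len(grp),
                "agreement_pct": 100.0 * float((grp["error"] == 0).mean()),
                "mean_error": float(grp["error"].mean()),
            }
        )
    rows.append(
        {
            "predicted": "overall",
            "n": len(frame),
            "agreement_pct": 100.0 * float((frame["error"] == 0).mean()),
            "mean_error": float(frame["error"].mean()),
        }
    )
    return pd.DataFrame(rows).set_index("predicted")
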