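"""Six-class gesture MLP with an online-backpropagation training contract.

The network mirrors the behavioral contract of the classic Weka-style
multilayer perceptron this pipeline was designed around: one hidden layer
of ``H`` sigmoid units, six sigmoid outputs trained on one-hot targets with
squared error, per-sample weight updates with learning rate ``L`` and
momentum ``M`` for ``N`` epochs, seeded weight initialization and per-epoch
shuffling, and per-feature min-max normalization to [-1, 1] learned from
the training split only.

Training is deterministic: the same data order, hyperparameters, and seed
produce bit-identical weights.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .data import GestureDataset, N_CLASSES
from .features import N_FEATURES

__all__ = [
    "MLPHyperparams",
    "GestureModel",
    "train_mlp",
    "predict",
    "predict_batch",
    "save_model",
    "load_model",
    "ModelFormatError",
]

MODEL_FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed or has the wrong version."""


@dataclasses.dataclass(frozen=True)
class MLPHyperparams:
    """Learning rate L, momentum M, hidden units H, seed S, epochs N.

    Defaults are the operating point the pipeline was tuned to.  Note these
    live in a different namespace than the face measures that happen to
    share letters (L, M, N are also measure names).
    """

    learning_rate: float = 0.2045
    momentum: float = 0.1909
    hidden_units: int = 95
    seed: int = 0
    epochs: int = 5000

    def __post_init__(self) -> None:
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must be in (0, 1]")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclasses.dataclass
class GestureModel:
    """Trained weights plus the normalization learned from the training fold."""

    w_hidden: np.ndarray   # (n_features, H)
    b_hidden: np.ndarray   # (H,)
    w_out: np.ndarray      # (H, n_classes)
    b_out: np.ndarray      # (n_classes,)
    feat_min: np.ndarray   # (n_features,)
    feat_max: np.ndarray   # (n_features,)
    classes: tuple[int, ...] = tuple(range(N_CLASSES))
    hyperparams: MLPHyperparams = dataclasses.field(default_factory=MLPHyperparams)

    @property
    def n_features(self) -> int:
        return self.w_hidden.shape[0]

    def normalize(self, X: np.ndarray) -> np.ndarray:
        """Min-max scale to [-1, 1] with the *training* extrema; constant
        features map to 0."""
        span = self.feat_max - self.feat_min
        safe = np.where(span == 0.0, 1.0, span)
        Z = 2.0 * (X - self.feat_min) / safe - 1.0
        return np.where(span == 0.0, 0.0, Z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _resolve_xy(train) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(train, GestureDataset):
        return train.feature_matrix(), train.labels
    X, y = train
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int)


def train_mlp(train, hp: MLPHyperparams | None = None, *,
              n_classes: int = N_CLASSES) -> GestureModel:
    """Train the gesture MLP on a dataset or an ``(X, y)`` pair.

    Parameters
    ----------
    train
        A :class:`GestureDataset` with extracted features, or a tuple
        ``(X, y)`` with ``X`` of shape (n_samples, 29) and integer labels.
    hp
        Hyperparameters; defaults to the tuned operating point.
    """
    hp = hp or MLPHyperparams()
    X, y = _resolve_xy(train)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training set must be a non-empty 2-D feature matrix")
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if np.any(y < 0) or np.any(y >= n_classes):
        raise ValueError(f"labels must be in 0..{n_classes - 1}")

    feat_min = X.min(axis=0)
    feat_max = X.max(axis=0)
    model = GestureModel(
        w_hidden=np.empty(0), b_hidden=np.empty(0),
        w_out=np.empty(0), b_out=np.empty(0),
        feat_min=feat_min, feat_max=feat_max,
        classes=tuple(range(n_classes)), hyperparams=hp,
    )
    Z = model.normalize(X)
    T = np.zeros((len(y), n_classes))
    T[np.arange(len(y)), y] = 1.0

    rng = np.random.RandomState(hp.seed)
    n_in, n_hid = X.shape[1], hp.hidden_units
    w1 = rng.uniform(-0.5, 0.5, size=(n_in, n_hid))
    b1 = rng.uniform(-0.5, 0.5, size=n_hid)
    w2 = rng.uniform(-0.5, 0.5, size=(n_hid, n_classes))
    b2 = rng.uniform(-0.5, 0.5, size=n_classes)
    vw1 = np.zeros_like(w1); vb1 = np.zeros_like(b1)
    vw2 = np.zeros_like(w2); vb2 = np.zeros_like(b2)

    lr, mom = hp.learning_rate, hp.momentum
    n = len(Z)
    for _ in range(hp.epochs):
        order = rng.permutation(n)
        for i in order:
            x = Z[i]
            h = _sigmoid(x @ w1 + b1)
            o = _sigmoid(h @ w2 + b2)
            # squared-error deltas through the sigmoids
            d_out = (o - T[i]) * o * (1.0 - o)
            d_hid = (w2 @ d_out) * h * (1.0 - h)
            vw2 = mom * vw2 - lr * np.outer(h, d_out)
            vb2 = mom * vb2 - lr * d_out
            vw1 = mom * vw1 - lr * np.outer(x, d_hid)
            vb1 = mom * vb1 - lr * d_hid
            w2 += vw2; b2 += vb2
            w1 += vw1; b1 += vb1

    model.w_hidden, model.b_hidden = w1, b1
    model.w_out, model.b_out = w2, b2
    return model


def _forward(model: GestureModel, Z: np.ndarray) -> np.ndarray:
    h = _sigmoid(Z @ model.w_hidden + model.b_hidden)
    return _sigmoid(h @ model.w_out + model.b_out)


def predict_batch(model: GestureModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and output activations for a feature matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    scores = _forward(model, model.normalize(X))
    return scores.argmax(axis=1), scores  # argmax ties break to lowest index


def predict(model: GestureModel, fv: np.ndarray) -> tuple[int, np.ndarray]:
    """Predicted label (argmax of output activations, ties to the lowest
    class index) and the raw 6-element score vector."""
    labels, scores = predict_batch(model, np.asarray(fv, dtype=float).reshape(1, -1))
    return int(labels[0]), scores[0]


# --------------------------------------------------------------------------
# persistence


def save_model(model: GestureModel, path: str | Path) -> None:
    payload = {
        "format": "palsygest-mlp",
        "version": MODEL_FORMAT_VERSION,
        "hyperparams": dataclasses.asdict(model.hyperparams),
        "classes": list(model.classes),
        "weights": {
            "w_hidden": model.w_hidden.tolist(),
            "b_hidden": model.b_hidden.tolist(),
            "w_out": model.w_out.tolist(),
            "b_out": model.b_out.tolist(),
        },
        "normalization": {
            "feat_min": model.feat_min.tolist(),
            "feat_max": model.feat_max.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> GestureModel:
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "palsygest-mlp":
        raise ModelFormatError("not a palsygest model file")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model version {payload.get('version')!r}; "
            f"expected {MODEL_FORMAT_VERSION}"
        )
    try:
        w = payload["weights"]
        norm = payload["normalization"]
        return GestureModel(
            w_hidden=np.asarray(w["w_hidden"], dtype=float),
            b_hidden=np.asarray(w["b_hidden"], dtype=float),
            w_out=np.asarray(w["w_out"], dtype=float),
            b_out=np.asarray(w["b_out"], dtype=float),
            feat_min=np.asarray(norm["feat_min"], dtype=float),
            feat_max=np.asarray(norm["feat_max"], dtype=float),
            classes=tuple(payload["classes"]),
            hyperparams=MLPHyperparams(**payload["hyperparams"]),
        )
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"malformed model payload: {exc}") from exc
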