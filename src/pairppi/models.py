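"""Classifier heads over Hadamard pair features.

The primary head is a 4-layer multilayer perceptron (hidden widths 1024,
512, 128, 16) with ReLU activations, a sigmoid output yielding an
interaction score in [0, 1], and binary cross-entropy loss, trained with
Adam for a fixed number of epochs. Random-forest (100 trees, unlimited
depth) and support-vector (RBF kernel, C=1, gamma='scale') heads are
provided for comparison at the same settings a practitioner would use.

Because the input is the elementwise product of the two member vectors,
every head's score is invariant under swapping the pair members.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and optimisation settings for the MLP head."""

    hidden_sizes: tuple[int, ...] = (1024, 512, 128, 16)
    epochs: int = 40
    threshold: float = 0.5
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 64

    def __post_init__(self) -> None:
        if not self.hidden_sizes or any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be nonempty and positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


@dataclass
class TrainedModel:
    """A fitted classifier head plus the metadata needed to apply it."""

    kind: str  # mlp | rf | svm
    params: object
    input_dim: int
    config: object = None
    history: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise ValueError(f"{path} does not contain a TrainedModel")
        return model


def _validate_training_inputs(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be N x D with one label per row")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training examples")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("labels must be binary (0/1)")
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    return X, y


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_from_logits(z: np.ndarray, y: np.ndarray) -> float:
    # mean of softplus(z) - y*z, numerically stable for large |z|
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


class _MLPParams:
    """Weights/biases plus the forward pass; backprop lives in train_mlp."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Return hidden activations (post-ReLU) and output logits."""
        acts = [X]
        h = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        z = (h @ self.W[-1] + self.b[-1]).ravel()
        return acts, z


def train_mlp(X: np.ndarray, y: np.ndarray, config: MLPConfig | None = None) -> TrainedModel:
    """Fit the MLP head by minibatch Adam on binary cross-entropy.

    Training is fully reproducible under the configured seed: weight
    initialisation and the per-epoch example shuffle both derive from it.
    The per-epoch mean training loss is recorded in ``history``.
    """
    config = config or MLPConfig()
    X, y = _validate_training_inputs(X, y)
    n, d = X.shape
    rng = np.random.default_rng(config.seed)
    params = _MLPParams([d, *config.hidden_sizes, 1], rng)

    # Adam state
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    mW = [np.zeros_like(W) for W in params.W]
    vW = [np.zeros_like(W) for W in params.W]
    mb = [np.zeros_like(b) for b in params.b]
    vb = [np.zeros_like(b) for b in params.b]
    t = 0

    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            acts, z = params.forward(xb)
            epoch_loss += _bce_from_logits(z, yb) * idx.size

            # backprop: d(loss)/d(logit) for mean BCE over the batch
            delta = ((_sigmoid(z) - yb) / idx.size)[:, None]
            grads_W: list[np.ndarray] = [None] * len(params.W)  # type: ignore[list-item]
            grads_b: list[np.ndarray] = [None] * len(params.b)  # type: ignore[list-item]
            for layer in range(len(params.W) - 1, -1, -1):
                grads_W[layer] = acts[layer].T @ delta
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ params.W[layer].T) * (acts[layer] > 0)

            t += 1
            corr1 = 1.0 - beta1**t
            corr2 = 1.0 - beta2**t
            for layer in range(len(params.W)):
                for g, p, m, v in (
                    (grads_W[layer], params.W[layer], mW, vW),
                    (grads_b[layer], params.b[layer], mb, vb),
                ):
                    m[layer] = beta1 * m[layer] + (1 - beta1) * g
                    v[layer] = beta2 * v[layer] + (1 - beta2) * g * g
                    p -= config.learning_rate * (m[layer] / corr1) / (
                        np.sqrt(v[layer] / corr2) + eps
                    )
        history.append(epoch_loss / n)

    return TrainedModel("mlp", params, d, config, history)


def train_rf(X: np.ndarray, y: np.ndarray, seed: int = 0) -> TrainedModel:
    """Random forest head: 100 trees, unlimited depth."""
    X, y = _validate_training_inputs(X, y)
    clf = RandomForestClassifier(n_estimators=100, max_depth=None, random_state=seed)
    clf.fit(X, y.astype(int))
    return TrainedModel("rf", clf, X.shape[1])


def train_svm(X: np.ndarray, y: np.ndarray, seed: int = 0) -> TrainedModel:
    """Support-vector head: RBF kernel, C=1, gamma='scale', with
    probability calibration so scores land in [0, 1]."""
    X, y = _validate_training_inputs(X, y)
    svc = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    clf = CalibratedClassifierCV(svc, ensemble=False)
    clf.fit(X, y.astype(int))
    return TrainedModel("svm", clf, X.shape[1])


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Score pair features: one interaction score in [0, 1] per row."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.zeros(0)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"input dim {model.input_dim}"
        )
    if model.kind == "mlp":
        _, z = model.params.forward(X)
        return _sigmoid(z)
    if model.kind in ("rf", "svm"):
        proba = model.params.predict_proba(X)
        return proba[:, list(model.params.classes_).index(1)]
    raise ValueError(f"unknown model kind {model.kind!r}")


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary decision at the >= threshold rule (a score exactly at the
    threshold is called an interaction)."""
    scores = np.asarray(scores, dtype=float)
    return (scores >= threshold).astype(int)
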