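"""Synonym classifier: a small fully connected network over the four
similarity scores.

Architecture 4-5-5-1: two hidden layers of five rectified-linear neurons
and a single logistic output read as the probability that the candidate
pair are synonyms.  Training is plain per-example stochastic gradient
descent on binary cross-entropy, with a seeded shuffle each epoch and
early stopping on a held-out validation split.  Weight updates, the
initialization and the shuffles all flow from one seed, so fitting is
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .similarity import SimilarityVector


@dataclass
class SynonymExample:
    """A labeled candidate pair with its similarity features."""

    pair: tuple[str, str]
    features: SimilarityVector
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class SynonymMLP(ClassifierMixin, BaseEstimator):
    """Multilayer perceptron fusing similarity scores into a synonym call.

    Parameters
    ----------
    hidden_layer_sizes : sizes of the hidden layers (default two layers of
        five neurons).
    learning_rate : constant SGD step size.
    epochs : maximum training epochs (early stopping may end sooner).
    validation_fraction : share of the data held out to monitor the error.
    patience : epochs without validation improvement before stopping
        (generous, because per-example SGD makes the monitored loss noisy).
    threshold : probability cut for labelling a pair a synonym.
    balance : resample negatives to a 1:1 ratio with positives before
        training (candidate generation is heavily negative-skewed).
    random_state : seed for initialization, splits, resampling, shuffling.

    Attributes
    ----------
    weights_, biases_ : per-layer parameters (input -> output order).
    layer_sizes_ : e.g. ``[4, 5, 5, 1]``.
    loss_curve_ : training loss per epoch.
    training_meta_ : seed, epochs run, learning rate, final losses,
        initialization scheme.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (5, 5),
        learning_rate: float = 0.01,
        epochs: int = 200,
        validation_fraction: float = 0.2,
        patience: int = 25,
        threshold: float = 0.5,
        balance: bool = True,
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.threshold = threshold
        self.balance = balance
        self.random_state = random_state

    # ---------------------------------------------------------------- setup
    def initialize(self, n_features: int = 4) -> "SynonymMLP":
        """Draw initial weights without training (uniform in [-r, r] with
        r = 1/sqrt(fan_in); biases zero)."""
        rng = np.random.default_rng(self.random_state)
        self.layer_sizes_ = [n_features, *self.hidden_layer_sizes, 1]
        self.weights_ = []
        self.biases_ = []
        for fan_in, fan_out in zip(self.layer_sizes_[:-1], self.layer_sizes_[1:]):
            r = 1.0 / np.sqrt(fan_in)
            self.weights_.append(rng.uniform(-r, r, size=(fan_in, fan_out)))
            self.biases_.append(np.zeros(fan_out))
        self.classes_ = np.array([0, 1])
        return self

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if not np.isfinite(X).all() or (X < 0).any() or (X > 1).any():
            raise ValueError("similarity features must lie in [0, 1]")
        return X

    # ------------------------------------------------------------- training
    def fit(self, X, y) -> "SynonymMLP":
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if X.shape[0] == 0:
            raise ValueError("training data is empty")
        classes = np.unique(y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise ValueError("training data must contain both classes (0 and 1)")

        rng = np.random.default_rng(self.random_state)
        self.initialize(n_features=X.shape[1])

        # stratified validation split
        n = X.shape[0]
        val_idx: list[int] = []
        for cls in (0.0, 1.0):
            idx = np.flatnonzero(y == cls)
            idx = idx[rng.permutation(idx.size)]
            n_val = int(round(idx.size * self.validation_fraction))
            val_idx.extend(idx[:n_val].tolist())
        val_mask = np.zeros(n, dtype=bool)
        val_mask[val_idx] = True
        X_val, y_val = X[val_mask], y[val_mask]
        X_tr, y_tr = X[~val_mask], y[~val_mask]

        if self.balance:
            pos = np.flatnonzero(y_tr == 1.0)
            neg = np.flatnonzero(y_tr == 0.0)
            if neg.size != pos.size and pos.size > 0:
                neg = rng.choice(neg, size=pos.size, replace=neg.size < pos.size)
                keep = np.concatenate([pos, neg])
                X_tr, y_tr = X_tr[keep], y_tr[keep]

        best_val = np.inf
        best_snapshot = None
        wait = 0
        self.loss_curve_ = []
        epochs_run = 0
        for _ in range(self.epochs):
            epochs_run += 1
            order = rng.permutation(X_tr.shape[0])
            for i in order:
                self._sgd_step(X_tr[i], y_tr[i])
            train_loss = self._log_loss(X_tr, y_tr)
            if not np.isfinite(train_loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epochs_run}"
                )
            self.loss_curve_.append(train_loss)
            val_loss = self._log_loss(X_val, y_val) if X_val.shape[0] else train_loss
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_snapshot = (
                    [w.copy() for w in self.weights_],
                    [b.copy() for b in self.biases_],
                )
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
        if best_snapshot is not None:
            self.weights_, self.biases_ = best_snapshot
        self.training_meta_ = {
            "seed": self.random_state,
            "epochs_run": epochs_run,
            "learning_rate": self.learning_rate,
            "final_loss": float(self.loss_curve_[-1]),
            "best_val_loss": float(best_val) if np.isfinite(best_val) else None,
            "init": "uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)), zero biases",
        }
        return self

    def _sgd_step(self, x: np.ndarray, label: float) -> None:
        acts = [x]
        for w, b in zip(self.weights_[:-1], self.biases_[:-1]):
            acts.append(_relu(acts[-1] @ w + b))
        p = _sigmoid(acts[-1] @ self.weights_[-1] + self.biases_[-1])
        # output delta of sigmoid + binary cross-entropy
        delta = p - label
        for layer in range(len(self.weights_) - 1, -1, -1):
            grad_w = np.outer(acts[layer], delta)
            grad_b = delta
            if layer > 0:
                delta = (self.weights_[layer] @ delta) * (acts[layer] > 0)
            self.weights_[layer] -= self.learning_rate * grad_w
            self.biases_[layer] -= self.learning_rate * grad_b

    def _log_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(self._forward(X), 1e-12, 1.0 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))

    # ------------------------------------------------------------ inference
    def _forward(self, X: np.ndarray) -> np.ndarray:
        a = X
        for w, b in zip(self.weights_[:-1], self.biases_[:-1]):
            a = _relu(a @ w + b)
        return _sigmoid(a @ self.weights_[-1] + self.biases_[-1]).ravel()

    def _check_ready(self) -> None:
        if not hasattr(self, "weights_"):
            raise RuntimeError("SynonymMLP has no weights (call fit or initialize)")

    def predict_proba(self, X) -> np.ndarray:
        self._check_ready()
        p1 = self._forward(self._validate_X(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    def predict_pair(self, v: SimilarityVector | Sequence[float]) -> tuple[float, int]:
        """Probability and thresholded label for a single similarity vector."""
        feats = v.as_tuple() if isinstance(v, SimilarityVector) else tuple(v)
        p = float(self.predict_proba([list(feats)])[0, 1])
        return p, int(p >= self.threshold)

    # ---------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        self._check_ready()
        payload = {
            "layer_sizes": self.layer_sizes_,
            "weights": [[float(x) for x in w.ravel()] for w in self.weights_],
            "biases": [[float(x) for x in b] for b in self.biases_],
            "threshold": self.threshold,
            "params": self.get_params(),
            "training_meta": getattr(self, "training_meta_", None),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SynonymMLP":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        model = cls(**payload["params"])
        sizes = payload["layer_sizes"]
        model.layer_sizes_ = sizes
        model.weights_ = [
            np.array(w, dtype=float).reshape(fan_in, fan_out)
            for w, fan_in, fan_out in zip(payload["weights"], sizes[:-1], sizes[1:])
        ]
        model.biases_ = [np.array(b, dtype=float) for b in payload["biases"]]
        model.threshold = payload["threshold"]
        model.classes_ = np.array([0, 1])
        if payload.get("training_meta"):
            model.training_meta_ = payload["training_meta"]
        return model


# ------------------------------------------------------- functional wrappers
def init_mlp(seed: int, n_features: int = 4) -> SynonymMLP:
    """Freshly initialized (untrained) 4-5-5-1 network."""
    return SynonymMLP(random_state=seed).initialize(n_features=n_features)


def train_mlp(
    model: SynonymMLP,
    data: Sequence[SynonymExample],
    epochs: int | None = None,
    learning_rate: float | None = None,
    validation_fraction: float | None = None,
    seed: int | None = None,
) -> SynonymMLP:
    """Fit ``model`` on labeled examples, optionally overriding
    hyperparameters."""
    if not data:
        raise ValueError("training data is empty")
    overrides = {
        "epochs": epochs,
        "learning_rate": learning_rate,
        "validation_fraction": validation_fraction,
        "random_state": seed,
    }
    model.set_params(**{k: v for k, v in overrides.items() if v is not None})
    X = np.array([ex.features.as_tuple() for ex in data], dtype=float)
    y = np.array([ex.label for ex in data], dtype=int)
    return model.fit(X, y)


def predict_synonym(model: SynonymMLP, v: SimilarityVector) -> tuple[float, int]:
    """(synonym probability, thresholded 0/1 label) for one pair."""
    return model.predict_pair(v)
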