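"""The 18-input / 7-output emotion classifier.

A fully-connected network maps the 18 per-recording statistics to a softmax
distribution over the seven basic emotions (Afraid, Angry, Disgusted, Happy,
Neutral, Sad, Surprised). The default architecture is the hidden stack
[32, 64, 128, 64, 32] with ReLU activations, dropout 0.2, an L2 weight
penalty of 0.01, mean-squared-error loss against one-hot targets, and early
stopping on the validation loss.

Organisation follows the model/results idiom: build an
:class:`EmotionClassifier` from a feature matrix and labels, call
``fit()`` and work with the returned :class:`EmotionClassifierResults`
(per-epoch history, prediction, evaluation, a ``summary()`` table,
save/load). Thin functional wrappers (:func:`split_dataset`,
:func:`train_model`, :func:`predict`, :func:`evaluate`) expose the same
operations procedurally.

The trainer is a compact self-contained numpy implementation (Adam,
inverted dropout, L2, patience-based early stopping with best-weight
restore) so that the loss/dropout combination above is exactly the one
specified rather than an approximation by another objective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, NotFittedError
from .features import FeatureVector, VECTOR_COLUMNS
from .signal_sim import EMOTION_LABELS


@dataclass(frozen=True)
class ModelConfig:
    """Training hyperparameters.

    min_delta is the minimum validation-loss improvement that resets the
    early-stopping patience counter; for an MSE on [0, 1] the usable default
    is 1e-3. Optimizer (Adam), learning rate, batch size and patience are
    package defaults, all logged with the trained model.
    """

    hidden_layers: tuple[int, ...] = (32, 64, 128, 64, 32)
    dropout_rate: float = 0.2
    l2_penalty: float = 0.01
    early_stop_monitor: str = "validation loss"
    early_stop_min_delta: float = 1e-3
    early_stop_patience: int = 20
    max_epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    loss: str = "mse"  # or "cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_layers):
            raise InvalidParameterError("hidden layer sizes must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InvalidParameterError("dropout_rate must lie in [0, 1)")
        if self.l2_penalty < 0:
            raise InvalidParameterError("l2_penalty must be non-negative")
        if self.loss not in ("mse", "cross_entropy"):
            raise InvalidParameterError("loss must be 'mse' or 'cross_entropy'")
        if self.max_epochs < 1:
            raise InvalidParameterError("max_epochs must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test/validation split fractions (default 80/10/10)."""

    train_fraction: float = 0.8
    test_fraction: float = 0.1
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_fraction + self.test_fraction + self.validation_fraction
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError("split fractions must sum to 1")


@dataclass
class EmotionEstimate:
    """A probability distribution over the seven emotion labels."""

    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.probabilities) != set(EMOTION_LABELS):
            raise InvalidParameterError("estimate must cover exactly the 7 labels")
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-6 or any(p < 0 for p in self.probabilities.values()):
            raise InvalidParameterError("probabilities must be non-negative and sum to 1")

    @property
    def argmax_label(self) -> str:
        return max(EMOTION_LABELS, key=lambda lb: self.probabilities[lb])

    def as_array(self) -> np.ndarray:
        return np.asarray([self.probabilities[lb] for lb in EMOTION_LABELS])


def split_dataset(
    vectors: Sequence[FeatureVector], spec: SplitSpec = SplitSpec()
) -> tuple[list[FeatureVector], list[FeatureVector], list[FeatureVector]]:
    """Random disjoint (train, test, validation) partitions.

    Test and validation sizes are round(fraction * n); the rounding
    remainder is absorbed into the training partition. Deterministic for a
    given spec.seed.
    """
    n = len(vectors)
    if n < 10:
        raise InvalidParameterError("need at least 10 vectors to split")
    if any(v.label is None for v in vectors):
        raise InvalidParameterError("all vectors must be labelled before splitting")
    n_test = int(round(spec.test_fraction * n))
    n_val = int(round(spec.validation_fraction * n))
    n_train = n - n_test - n_val
    if min(n_train, n_test, n_val) < 1:
        raise InvalidParameterError("each partition must receive at least one vector")
    rng = np.random.default_rng(spec.seed & 0x7FFFFFFF)
    order = rng.permutation(n)
    train = [vectors[i] for i in order[:n_train]]
    test = [vectors[i] for i in order[n_train : n_train + n_test]]
    val = [vectors[i] for i in order[n_train + n_test :]]
    return train, test, val


def _to_xy(vectors: Sequence[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([v.values for v in vectors])
    y = np.asarray([EMOTION_LABELS.index(v.label) for v in vectors])
    return X, y


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Network:
    """Weights and forward/backward passes of the dense stack."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization suits the ReLU hidden units
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    def forward(
        self,
        X: np.ndarray,
        dropout_rate: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        """Returns (probabilities, cache for backward)."""
        a = X
        cache = []
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            if i < n_layers - 1:
                h = np.maximum(z, 0.0)
                if dropout_rate > 0.0 and rng is not None:
                    mask = (rng.random(h.shape) >= dropout_rate) / (1.0 - dropout_rate)
                    h = h * mask
                else:
                    mask = None
                cache.append((a, z, mask))
                a = h
            else:
                cache.append((a, z, None))
        probs = _softmax(z)
        return probs, cache

    def backward(self, probs, Y, cache, loss, l2):
        """Gradients of the batch loss (plus L2) w.r.t. weights and biases.

        The L2 penalty follows the scikit-learn convention
        (l2 / (2 n_batch)) * sum(W^2), i.e. the gradient contribution is
        l2 * W / n_batch, keeping the penalty commensurate with the
        per-sample-averaged data loss.
        """
        n = probs.shape[0]
        if loss == "mse":
            # L = mean over samples and classes of (p - y)^2, p = softmax(z)
            dL_dp = 2.0 * (probs - Y) / (n * probs.shape[1])
            inner = np.sum(dL_dp * probs, axis=1, keepdims=True)
            delta = probs * (dL_dp - inner)  # softmax Jacobian applied
        else:  # cross-entropy with softmax: the classic shortcut
            delta = (probs - Y) / n
        grads_W = []
        grads_b = []
        for i in range(len(self.weights) - 1, -1, -1):
            a_prev, z, mask = cache[i]
            gW = a_prev.T @ delta + (l2 / n) * self.weights[i]
            gb = delta.sum(axis=0)
            grads_W.append(gW)
            grads_b.append(gb)
            if i > 0:
                da = delta @ self.weights[i].T
                _, z_prev, mask_prev = cache[i - 1]
                if mask_prev is not None:
                    da = da * mask_prev
                delta = da * (z_prev > 0.0)
        grads_W.reverse()
        grads_b.reverse()
        return grads_W, grads_b


class EmotionClassifier:
    """Model object: feature matrix + labels, ready to ``fit()``.

    Parameters
    ----------
    X, y : training design matrix (n, 18) and integer or string labels.
    validation : optional (X_val, y_val) pair monitored for early stopping;
        when omitted, a fraction of the training data is held out.
    config : ModelConfig hyperparameters.
    """

    n_features = 18
    n_classes = len(EMOTION_LABELS)

    def __init__(self, X, y, validation=None, config: ModelConfig = ModelConfig()):
        self.X = np.asarray(X, dtype=float)
        self.y = self._encode_labels(y)
        if self.X.ndim != 2 or self.X.shape[1] != self.n_features:
            raise InvalidParameterError(
                f"design matrix must be (n, {self.n_features}), got {self.X.shape}"
            )
        if self.X.shape[0] == 0:
            raise InvalidParameterError("training partition is empty")
        if len(self.y) != self.X.shape[0]:
            raise InvalidParameterError("X and y lengths differ")
        if validation is not None:
            Xv, yv = validation
            self.X_val = np.asarray(Xv, dtype=float)
            self.y_val = self._encode_labels(yv)
            if self.X_val.ndim != 2 or self.X_val.shape[1] != self.n_features:
                raise InvalidParameterError("validation matrix has wrong width")
            if self.X_val.shape[0] == 0:
                raise InvalidParameterError("validation partition is empty")
        else:
            self.X_val = None
            self.y_val = None
        self.config = config

    @staticmethod
    def _encode_labels(y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "USO":
            try:
                return np.asarray([EMOTION_LABELS.index(str(lb)) for lb in y])
            except ValueError as exc:
                raise InvalidParameterError(f"unknown emotion label: {exc}") from exc
        y = y.astype(int)
        if y.size and (y.min() < 0 or y.max() >= len(EMOTION_LABELS)):
            raise InvalidParameterError("integer labels must lie in [0, 7)")
        return y

    @classmethod
    def from_vectors(
        cls,
        train: Sequence[FeatureVector],
        validation: Sequence[FeatureVector] | None = None,
        config: ModelConfig = ModelConfig(),
    ) -> "EmotionClassifier":
        X, y = _to_xy(train)
        val = _to_xy(validation) if validation else None
        return cls(X, y, validation=val, config=config)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        label_column: str = "label",
        validation: pd.DataFrame | None = None,
        config: ModelConfig = ModelConfig(),
    ) -> "EmotionClassifier":
        cols = list(VECTOR_COLUMNS)
        X = frame[cols].to_numpy(float)
        y = frame[label_column].to_numpy()
        val = None
        if validation is not None:
            val = (validation[cols].to_numpy(float), validation[label_column].to_numpy())
        return cls(X, y, validation=val, config=config)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "EmotionClassifierResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)

        X, y = self.X, self.y
        if self.X_val is not None:
            X_val, y_val = self.X_val, self.y_val
        else:
            # hold out 10% (at least 1 sample) for the early-stopping monitor
            n = X.shape[0]
            n_val = max(1, int(round(0.1 * n))) if n > 1 else 0
            order = rng.permutation(n)
            val_idx, train_idx = order[:n_val], order[n_val:]
            if train_idx.size == 0:
                train_idx, val_idx = order, order
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[train_idx], y[train_idx]

        # standardize inputs on training statistics; the statistics travel
        # with the model so prediction is self-contained
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0.0] = 1.0
        Xs = (X - mu) / sd
        Xv = (X_val - mu) / sd

        Y = np.eye(self.n_classes)[y]
        Yv = np.eye(self.n_classes)[y_val]

        sizes = [self.n_features, *cfg.hidden_layers, self.n_classes]
        net = _Network(sizes, rng)

        # Adam state
        mW = [np.zeros_like(w) for w in net.weights]
        vW = [np.zeros_like(w) for w in net.weights]
        mb = [np.zeros_like(b) for b in net.biases]
        vb = [np.zeros_like(b) for b in net.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        def eval_loss(Xe, Ye):
            probs, _ = net.forward(Xe)
            if cfg.loss == "mse":
                return float(np.mean((probs - Ye) ** 2))
            p = np.clip(np.sum(probs * Ye, axis=1), 1e-12, None)
            return float(-np.mean(np.log(p)))

        history = {"epoch": [], "train_mse": [], "val_mse": [], "val_accuracy": []}
        best_loss = np.inf
        best_weights = None
        patience_left = cfg.early_stop_patience
        n_train = Xs.shape[0]

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n_train)
            for start in range(0, n_train, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                probs, cache = net.forward(Xs[idx], cfg.dropout_rate, rng)
                gW, gb = net.backward(probs, Y[idx], cache, cfg.loss, cfg.l2_penalty)
                step += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for i in range(len(net.weights)):
                    mW[i] = beta1 * mW[i] + (1 - beta1) * gW[i]
                    vW[i] = beta2 * vW[i] + (1 - beta2) * gW[i] ** 2
                    net.weights[i] -= lr_t * mW[i] / (np.sqrt(vW[i]) + eps)
                    mb[i] = beta1 * mb[i] + (1 - beta1) * gb[i]
                    vb[i] = beta2 * vb[i] + (1 - beta2) * gb[i] ** 2
                    net.biases[i] -= lr_t * mb[i] / (np.sqrt(vb[i]) + eps)

            train_loss = eval_loss(Xs, Y)
            val_loss = eval_loss(Xv, Yv)
            val_probs, _ = net.forward(Xv)
            val_acc = float(np.mean(val_probs.argmax(axis=1) == y_val))
            history["epoch"].append(epoch)
            history["train_mse"].append(train_loss)
            history["val_mse"].append(val_loss)
            history["val_accuracy"].append(val_acc)

            if val_loss < best_loss - cfg.early_stop_min_delta:
                best_loss = val_loss
                best_weights = (
                    [w.copy() for w in net.weights],
                    [b.copy() for b in net.biases],
                )
                patience_left = cfg.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

        if best_weights is not None:
            net.weights, net.biases = best_weights

        return EmotionClassifierResults(
            model=self,
            network=net,
            input_mean=mu,
            input_std=sd,
            history=pd.DataFrame(history),
        )


class EmotionClassifierResults:
    """A fitted emotion classifier: weights, training history, diagnostics."""

    def __init__(self, model, network, input_mean, input_std, history):
        self.model = model
        self._net = network
        self.input_mean = input_mean
        self.input_std = input_std
        self.history = history
        self.labels = EMOTION_LABELS

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != EmotionClassifier.n_features:
            raise InvalidParameterError(
                f"expected {EmotionClassifier.n_features} features, got {X.shape[1]}"
            )
        Xs = (X - self.input_mean) / self.input_std
        probs, _ = self._net.forward(Xs)  # dropout disabled at inference
        return probs

    def predict(self, vector) -> EmotionEstimate:
        """Estimate for a single FeatureVector or length-18 array."""
        values = vector.values if isinstance(vector, FeatureVector) else np.asarray(vector)
        probs = self.predict_proba(values.reshape(1, -1))[0]
        return EmotionEstimate({lb: float(p) for lb, p in zip(self.labels, probs)})

    def evaluate(self, partition, y=None) -> dict:
        """Accuracy, loss and per-class confusion counts on a labelled partition.

        Accepts either a sequence of labelled FeatureVectors or an (X, y) pair.
        """
        if y is None:
            vectors = list(partition)
            if not vectors:
                raise InvalidParameterError("cannot evaluate an empty partition")
            if any(v.label is None for v in vectors):
                raise InvalidParameterError("evaluation partition must be labelled")
            X, y_idx = _to_xy(vectors)
        else:
            X = np.asarray(partition, dtype=float)
            if X.shape[0] == 0:
                raise InvalidParameterError("cannot evaluate an empty partition")
            y_idx = EmotionClassifier._encode_labels(y)
        probs = self.predict_proba(X)
        pred = probs.argmax(axis=1)
        Y = np.eye(EmotionClassifier.n_classes)[y_idx]
        mse = float(np.mean((probs - Y) ** 2))
        confusion = np.zeros((7, 7), dtype=int)
        np.add.at(confusion, (y_idx, pred), 1)
        return {
            "accuracy": float(np.mean(pred == y_idx)),
            "mse": mse,
            "confusion": pd.DataFrame(confusion, index=self.labels, columns=self.labels),
            "n": int(X.shape[0]),
        }

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        h = self.history
        lines = [
            "Emotion classifier results",
            "=" * 48,
            f"Architecture:      18 -> {list(cfg.hidden_layers)} -> 7 (softmax)",
            f"Loss:              {cfg.loss} (one-hot targets)",
            f"Dropout / L2:      {cfg.dropout_rate} / {cfg.l2_penalty}",
            f"Epochs run:        {len(h)} (max {cfg.max_epochs})",
            f"Final train MSE:   {h['train_mse'].iloc[-1]:.5f}",
            f"Best val MSE:      {h['val_mse'].min():.5f}",
            f"Final val acc:     {h['val_accuracy'].iloc[-1]:.3f}",
            f"Train samples:     {self.model.X.shape[0]}",
            "=" * 48,
        ]
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Persist as a JSON header plus a .npz weight blob alongside it."""
        path = Path(path)
        header = {
            "config": {**asdict(self.model.config), "hidden_layers": list(self.model.config.hidden_layers)},
            "labels": list(self.labels),
            "feature_order": list(VECTOR_COLUMNS),
            "sizes": self._net.sizes,
        }
        path.write_text(json.dumps(header, indent=2) + "\n")
        blob = {"input_mean": self.input_mean, "input_std": self.input_std}
        for i, (w, b) in enumerate(zip(self._net.weights, self._net.biases)):
            blob[f"W{i}"] = w
            blob[f"b{i}"] = b
        np.savez(path.with_suffix(".npz"), **blob)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "EmotionClassifierResults":
        path = Path(path)
        header = json.loads(path.read_text())
        blob = np.load(path.with_suffix(".npz"))
        cfg_d = dict(header["config"])
        cfg_d["hidden_layers"] = tuple(cfg_d["hidden_layers"])
        cfg = ModelConfig(**cfg_d)
        net = _Network(header["sizes"], np.random.default_rng(0))
        n_layers = len(header["sizes"]) - 1
        net.weights = [blob[f"W{i}"] for i in range(n_layers)]
        net.biases = [blob[f"b{i}"] for i in range(n_layers)]
        dummy = EmotionClassifier(
            np.zeros((1, 18)), np.zeros(1, dtype=int), config=cfg
        )
        return cls(
            model=dummy,
            network=net,
            input_mean=blob["input_mean"],
            input_std=blob["input_std"],
            history=pd.DataFrame(
                {"epoch": [], "train_mse": [], "val_mse": [], "val_accuracy": []}
            ),
        )


# -- procedural wrappers matching the operation surface ----------------------

def train_model(
    train: Sequence[FeatureVector],
    validation: Sequence[FeatureVector],
    config: ModelConfig = ModelConfig(),
) -> EmotionClassifierResults:
    """Fit the classifier on labelled feature vectors; returns the results
    object whose ``history`` frame holds the per-epoch train/validation MSE."""
    if not train or not validation:
        raise InvalidParameterError("training and validation partitions must be non-empty")
    return EmotionClassifier.from_vectors(train, validation, config).fit()


def predict(results: EmotionClassifierResults, vector: FeatureVector) -> EmotionEstimate:
    if not isinstance(results, EmotionClassifierResults):
        raise NotFittedError("predict requires a fitted EmotionClassifierResults")
    return results.predict(vector)


def evaluate(results: EmotionClassifierResults, partition: Sequence[FeatureVector]) -> dict:
    return results.evaluate(partition)
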