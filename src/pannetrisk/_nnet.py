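"""Seeded multilayer softmax network trained with momentum SGD.

This is the configurable "backbone" behind the tissue and metastasis tile
classifiers.  It is deliberately small: tiles are reduced to pooled pixel
features (see :func:`tile_features`) and fed through one or two dense layers
ending in a softmax.  What matters for the pipeline is not the capacity of
the network but the training contract — per-epoch reshuffling from an
explicit seed, momentum SGD with L2 weight decay and a step learning-rate
decay, a per-class training-accuracy stopping rule, and a penultimate
feature layer that downstream embedding steps can read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

__all__ = ["TrainingSchedule", "SoftmaxNet", "tile_features"]


@dataclass
class TrainingSchedule:
    """Hyperparameters of one SGD training run.

    Defaults mirror the tissue-annotation schedule: momentum 0.9, batch
    size 35 tiles, learning rate 1e-4, training until every class's
    training accuracy reaches ``per_class_accuracy_stop`` (0.99) or
    ``max_epochs`` is hit.
    """

    learning_rate: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 35
    max_epochs: int = 50
    per_class_accuracy_stop: float | None = 0.99
    lr_decay_factor: float | None = None
    lr_decay_after_epochs: int | None = None
    l2_penalty: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if self.max_epochs <= 0:
            raise ValueError("max_epochs must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if self.per_class_accuracy_stop is not None and not (
            0.0 <= self.per_class_accuracy_stop <= 1.0
        ):
            raise ValueError("per_class_accuracy_stop must be in [0, 1]")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be non-negative")


def tile_features(pixels: np.ndarray, pool: int = 4) -> np.ndarray:
    """Reduce an H×W×3 tile to a fixed-length feature vector.

    A coarse ``pool``×``pool`` area-resampled thumbnail (color/layout
    signal) is concatenated with intensity statistics that summarize
    texture: per-channel mean/sd, gradient-magnitude mean/sd, gray-level
    quantiles and dark-pixel fractions.  Deterministic; 70 features at the
    default pool.
    """
    img = np.asarray(pixels, dtype=np.float64) / 255.0
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H×W×3 tile")
    small = resize(img, (pool, pool, 3), anti_aliasing=True, mode="reflect")
    gray = img.mean(axis=2)
    gy, gx = np.gradient(gray)
    gmag = np.hypot(gx, gy)
    stats = np.concatenate(
        [
            img.mean(axis=(0, 1)),
            img.std(axis=(0, 1)),
            [gmag.mean(), gmag.std()],
            np.quantile(gray, (0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95, 0.99)),
            [(gray < t).mean() for t in (0.3, 0.4, 0.5, 0.6, 0.7)],
        ]
    )
    return np.concatenate([small.ravel(), stats])


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class SoftmaxNet:
    """Dense network: input -> hidden layers (tanh) -> softmax.

    The last hidden layer is the penultimate feature layer exposed via
    :meth:`penultimate`.
    """

    input_dim: int
    n_classes: int
    hidden_dims: tuple[int, ...] = (64,)
    seed: int = 0
    weights_: list[np.ndarray] = field(default_factory=list, repr=False)
    biases_: list[np.ndarray] = field(default_factory=list, repr=False)
    loss_trace_: list[float] = field(default_factory=list, repr=False)
    epochs_run_: int = 0
    converged_: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(self.seed)
        dims = (self.input_dim, *self.hidden_dims, self.n_classes)
        self.weights_ = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.biases_ = [np.zeros(d) for d in dims[1:]]

    # -- forward ---------------------------------------------------------
    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X]
        h = X
        for W, b in zip(self.weights_[:-1], self.biases_[:-1]):
            h = np.tanh(h @ W + b)
            acts.append(h)
        acts.append(_softmax(h @ self.weights_[-1] + self.biases_[-1]))
        return acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=np.float64))[-1]

    def penultimate(self, X: np.ndarray) -> np.ndarray:
        """Activations of the last hidden layer (the feature layer)."""
        return self._forward(np.asarray(X, dtype=np.float64))[-2]

    # -- training --------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        schedule: TrainingSchedule,
        sample_weight: np.ndarray | None = None,
    ) -> "SoftmaxNet":
        """Momentum SGD with per-epoch reshuffling and a per-class stop rule.

        Training stops at the first epoch where every class's training
        accuracy reaches ``schedule.per_class_accuracy_stop``; otherwise at
        ``max_epochs`` with a warning.  With the stop rule set to ``None``
        the run always lasts exactly ``max_epochs`` epochs.  Optional
        per-sample weights rescale each sample's loss gradient (weights are
        normalized to mean 1).
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain at least two classes")
        if sample_weight is not None:
            sample_weight = np.asarray(sample_weight, dtype=np.float64)
            sample_weight = sample_weight / sample_weight.mean()
        rng = np.random.default_rng(schedule.seed)
        velocity_w = [np.zeros_like(W) for W in self.weights_]
        velocity_b = [np.zeros_like(b) for b in self.biases_]
        n = X.shape[0]
        lr = schedule.learning_rate
        self.loss_trace_ = []
        self.converged_ = False
        for epoch in range(schedule.max_epochs):
            if (
                schedule.lr_decay_factor is not None
                and schedule.lr_decay_after_epochs is not None
                and epoch == schedule.lr_decay_after_epochs
            ):
                lr = lr * schedule.lr_decay_factor
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, schedule.batch_size):
                idx = order[start : start + schedule.batch_size]
                acts = self._forward(X[idx])
                probs = acts[-1]
                m = idx.size
                onehot = np.zeros_like(probs)
                onehot[np.arange(m), y[idx]] = 1.0
                logp = np.log(np.clip(probs[np.arange(m), y[idx]], 1e-300, None))
                if sample_weight is None:
                    epoch_loss -= float(logp.sum())
                    delta = (probs - onehot) / m
                else:
                    w = sample_weight[idx]
                    epoch_loss -= float((w * logp).sum())
                    delta = (probs - onehot) * w[:, None] / m
                for layer in range(len(self.weights_) - 1, -1, -1):
                    grad_w = acts[layer].T @ delta + schedule.l2_penalty * self.weights_[layer]
                    grad_b = delta.sum(axis=0)
                    velocity_w[layer] = schedule.momentum * velocity_w[layer] - lr * grad_w
                    velocity_b[layer] = schedule.momentum * velocity_b[layer] - lr * grad_b
                    if layer > 0:
                        delta = (delta @ self.weights_[layer].T) * (1.0 - acts[layer] ** 2)
                    self.weights_[layer] += velocity_w[layer]
                    self.biases_[layer] += velocity_b[layer]
            self.loss_trace_.append(epoch_loss / n)
            self.epochs_run_ = epoch + 1
            if schedule.per_class_accuracy_stop is not None:
                pred = self.predict_proba(X).argmax(axis=1)
                per_class = [
                    float(np.mean(pred[y == c] == c)) for c in classes
                ]
                if all(a >= schedule.per_class_accuracy_stop for a in per_class):
                    self.converged_ = True
                    break
        else:
            if schedule.per_class_accuracy_stop is not None:
                warnings.warn(
                    "per-class accuracy stop rule not reached within "
                    f"{schedule.max_epochs} epochs",
                    stacklevel=2,
                )
        return self
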