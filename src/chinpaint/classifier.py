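"""Dense softmax classifier and the accuracy/improvement metrics.

The restoration benchmark deliberately uses a plain feed-forward network —
the point is to measure how much an inpainting filter helps label
prediction, not to maximize raw accuracy.  Architecture: flatten the 28x28
image to 784 inputs, two ReLU hidden layers of 64 units, a 10-unit softmax
head; categorical cross-entropy loss trained with Adam (lr 1e-3, beta1 0.9,
beta2 0.999, batch 32) for 10 epochs.  The implementation is a small,
self-contained numpy network with analytic backprop; fixed seeds make
training fully deterministic.

``improvement`` is the benchmark's headline metric: the relative accuracy
gain of classifying inpainted rather than damaged images,
``100 * (acc_with - acc_without) / acc_without``, reported as a
nearest-integer percentage (half away from zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import LabeledImageSet

__all__ = [
    "DenseClassifier",
    "build_classifier",
    "softmax",
    "cross_entropy",
    "train",
    "accuracy",
    "improvement",
]

LAYER_WIDTHS = (784, 64, 64, 10)
_PROB_FLOOR = 1e-12


@dataclass
class DenseClassifier:
    """Feed-forward 784-64-64-10 network: ReLU hidden layers, softmax head."""

    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)

    def layer_shapes(self) -> list[tuple[int, int]]:
        return [w.shape for w in self.weights]

    def parameter_counts(self) -> dict[str, int]:
        """Per-layer weight and bias counts (audit of the architecture)."""
        out = {}
        for k, (w, b) in enumerate(zip(self.weights, self.biases), start=1):
            out[f"layer{k}_weights"] = int(w.size)
            out[f"layer{k}_biases"] = int(b.size)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch of flattened [0,1] inputs."""
        a = np.atleast_2d(np.asarray(x, dtype=float))
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ w + b, 0.0)
        return softmax(a @ self.weights[-1] + self.biases[-1])

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Predicted labels for a stack of 8-bit images."""
        x = _flatten_images(images)
        return np.argmax(self.forward(x), axis=1)

    def copy(self) -> "DenseClassifier":
        return DenseClassifier(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
        )

    def save(self, path) -> None:
        arrays = {}
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{k}"] = w
            arrays[f"b{k}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "DenseClassifier":
        data = np.load(path)
        n_layers = len(data.files) // 2
        weights = [data[f"w{k}"] for k in range(n_layers)]
        biases = [data[f"b{k}"] for k in range(n_layers)]
        model = cls(weights=weights, biases=biases)
        expected = list(zip(LAYER_WIDTHS[:-1], LAYER_WIDTHS[1:]))
        if model.layer_shapes() != expected:
            raise ValueError(f"loaded layer shapes {model.layer_shapes()} != expected {expected}")
        return model


def build_classifier(seed: int = 0) -> DenseClassifier:
    """New 784-64-64-10 network with seeded Glorot-uniform weights, zero biases."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(LAYER_WIDTHS[:-1], LAYER_WIDTHS[1:]):
        limit = math.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return DenseClassifier(weights=weights, biases=biases)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, computed shift-invariantly for overflow safety."""
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    z = np.atleast_2d(z)
    shifted = z - z.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if single else p


def cross_entropy(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """Mean categorical cross-entropy; probabilities floored at 1e-12."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_prob = np.atleast_2d(np.asarray(y_prob, dtype=float))
    if y_true.shape != y_prob.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_prob.shape}")
    return float(-np.mean(np.sum(y_true * np.log(np.maximum(y_prob, _PROB_FLOOR)), axis=1)))


def _flatten_images(images: np.ndarray) -> np.ndarray:
    imgs = np.asarray(images, dtype=float)
    if imgs.ndim == 2:
        imgs = imgs[None]
    return imgs.reshape(imgs.shape[0], -1) / 255.0


def _one_hot(labels: np.ndarray, n_classes: int = 10) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def train(
    model: DenseClassifier,
    data: LabeledImageSet,
    epochs: int = 10,
    seed: int = 0,
    *,
    lr: float = 1e-3,
    beta1: float = 0.9,
    beta2: float = 0.999,
    adam_eps: float = 1e-8,
    batch_size: int = 32,
) -> DenseClassifier:
    """Train a copy of ``model`` with Adam on categorical cross-entropy.

    Images are normalized to [0, 1] and flattened; batches are reshuffled
    each epoch with a seeded generator, so training is deterministic.
    Returns the trained copy (``epochs=0`` returns an unchanged copy).
    """
    if len(data) == 0:
        raise ValueError("cannot train on an empty dataset")
    x_all = _flatten_images(data.images)
    y_all = _one_hot(data.labels)
    model = model.copy()
    params = model.weights + model.biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    rng = np.random.default_rng(seed)
    t = 0
    for _ in range(epochs):
        order = rng.permutation(len(x_all))
        for start in range(0, len(order), batch_size):
            batch = order[start : start + batch_size]
            grads = _gradients(model, x_all[batch], y_all[batch])
            t += 1
            for p, g, mk, vk in zip(params, grads, m, v):
                mk *= beta1
                mk += (1 - beta1) * g
                vk *= beta2
                vk += (1 - beta2) * g * g
                m_hat = mk / (1 - beta1**t)
                v_hat = vk / (1 - beta2**t)
                p -= lr * m_hat / (np.sqrt(v_hat) + adam_eps)
    return model


def _gradients(model: DenseClassifier, x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Backprop gradients of mean cross-entropy w.r.t. weights then biases."""
    activations = [x]
    a = x
    for w, b in zip(model.weights[:-1], model.biases[:-1]):
        a = np.maximum(a @ w + b, 0.0)
        activations.append(a)
    probs = softmax(a @ model.weights[-1] + model.biases[-1])
    n = len(x)
    delta = (probs - y) / n  # softmax + cross-entropy
    w_grads: list[np.ndarray] = []
    b_grads: list[np.ndarray] = []
    for k in range(len(model.weights) - 1, -1, -1):
        w_grads.append(activations[k].T @ delta)
        b_grads.append(delta.sum(axis=0))
        if k > 0:
            delta = (delta @ model.weights[k].T) * (activations[k] > 0)
    w_grads.reverse()
    b_grads.reverse()
    return w_grads + b_grads


def accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """Fraction of correct predictions."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {true.shape}")
    if predicted.size == 0:
        raise ValueError("accuracy of an empty prediction set is undefined")
    return float(np.mean(predicted == true))


def improvement(acc_with: float, acc_without: float) -> int:
    """Relative accuracy gain of the inpainting filter, in integer percent.

    ``100 * (acc_with - acc_without) / acc_without`` rounded to the nearest
    integer, halves away from zero.
    """
    if acc_without <= 0:
        raise ZeroDivisionError("improvement undefined when the baseline accuracy is 0")
    pct = 100.0 * (acc_with - acc_without) / acc_without
    # snap away binary round-off (e.g. 17.499999999999996) before rounding
    # halves away from zero
    pct = round(pct, 9)
    return int(math.floor(pct + 0.5)) if pct >= 0 else int(math.ceil(pct - 0.5))
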