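"""Skeleton-coordinate pose classifier.

A fully connected network maps the 32-dimensional vector of normalized
keypoint coordinates (x, y per part, in part-id order) to a probability
distribution over four output units.  Three units correspond to the
trained behaviors standing, walking and lying; the fourth unit,
"other", is reported but receives no training data by default — it is
reserved for transitional poses outside the three trained classes.

Architecture: 32 -> 128 -> 64 -> 16 -> 4, with batch normalization and
ReLU after each hidden layer and a softmax output.  Implemented directly
on numpy (explicit forward/backward passes and an Adam optimizer) so
training is lightweight and bit-reproducible from a seed.

Feature normalization translates and scales keypoints to the skeleton's
own bounding box so the features are invariant to where the animal
stands in the image and how large it appears; set ``normalize=False``
for raw pixel coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .skeleton import N_PARTS, CowSkeleton, skeleton_bbox

__all__ = [
    "CLASS_NAMES",
    "SkeletonFeature",
    "PoseProbabilities",
    "featurize",
    "PoseClassifier",
    "build_classifier",
    "train_classifier",
    "classify",
    "TrainingHistory",
]

CLASS_NAMES = ("standing", "walking", "lying", "other")
FEATURE_DIM = 2 * N_PARTS  # 32
_LAYER_SIZES = (FEATURE_DIM, 128, 64, 16, len(CLASS_NAMES))
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class SkeletonFeature:
    """32 reals: (x, y) per part in part-id order; missing parts are (0, 0)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (FEATURE_DIM,):
            raise ValueError(f"feature must have shape ({FEATURE_DIM},)")


@dataclass(frozen=True)
class PoseProbabilities:
    probs: np.ndarray

    @property
    def label(self) -> str:
        return CLASS_NAMES[int(np.argmax(self.probs))]


def featurize(skel: CowSkeleton, normalize: bool = True) -> SkeletonFeature:
    """Flatten a skeleton into the classifier's 32-vector.

    With ``normalize=True`` coordinates are translated/scaled to the
    skeleton's bounding box so each present part lands in [0, 1] per
    axis; a degenerate (zero-extent) axis is scaled by max(extent, 1)
    with a warning.  Parts with visibility 0 map to (0, 0).
    """
    out = np.zeros(FEATURE_DIM)
    if normalize:
        box = skeleton_bbox(skel)
        sx, sy = box.width, box.height
        if sx <= 0 or sy <= 0:
            warnings.warn("degenerate skeleton bbox; scaling by max(extent, 1)", stacklevel=2)
        sx, sy = max(sx, 1.0), max(sy, 1.0)
        ox, oy = box.xmin, box.ymin
    else:
        sx = sy = 1.0
        ox = oy = 0.0
    for kp in skel.keypoints:
        if kp.visibility == 0:
            continue
        i = 2 * (kp.part_id - 1)
        out[i] = (kp.x - ox) / sx
        out[i + 1] = (kp.y - oy) / sy
    return SkeletonFeature(out)


@dataclass
class _Dense:
    W: np.ndarray
    b: np.ndarray


@dataclass
class _BatchNorm:
    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray


class PoseClassifier:
    """The 32-128-64-16-4 batch-normalized MLP."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dense: list[_Dense] = []
        self.bn: list[_BatchNorm] = []
        for fan_in, fan_out in zip(_LAYER_SIZES[:-1], _LAYER_SIZES[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            W = rng.uniform(-limit, limit, size=(fan_in, fan_out))
            self.dense.append(_Dense(W, np.zeros(fan_out)))
        for width in _LAYER_SIZES[1:-1]:
            self.bn.append(
                _BatchNorm(np.ones(width), np.zeros(width), np.zeros(width), np.ones(width))
            )

    # -- parameter bookkeeping -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        params: list[np.ndarray] = []
        for d in self.dense:
            params.extend((d.W, d.b))
        for bn in self.bn:
            params.extend((bn.gamma, bn.beta))
        return params

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward ----------------------------------------------------

    def forward(self, X: np.ndarray, training: bool = False):
        """Return (probabilities, cache). ``X`` is (n, 32)."""
        cache: list[dict] = []
        h = X
        for li in range(3):
            d = self.dense[li]
            z = h @ d.W + d.b
            bn = self.bn[li]
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                bn.running_mean = _BN_MOMENTUM * bn.running_mean + (1 - _BN_MOMENTUM) * mu
                bn.running_var = _BN_MOMENTUM * bn.running_var + (1 - _BN_MOMENTUM) * var
            else:
                mu, var = bn.running_mean, bn.running_var
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * inv_std
            a = bn.gamma * zhat + bn.beta
            out = np.maximum(a, 0.0)
            cache.append({"h": h, "z": z, "zhat": zhat, "inv_std": inv_std, "a": a})
            h = out
        d = self.dense[3]
        logits = h @ d.W + d.b
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        cache.append({"h": h})
        return probs, cache

    def backward(self, probs: np.ndarray, cache: list[dict], y: np.ndarray):
        """Gradients of mean cross-entropy w.r.t. all parameters."""
        n = probs.shape[0]
        grads: dict[int, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        h3 = cache[3]["h"]
        gW3 = h3.T @ dlogits
        gb3 = dlogits.sum(axis=0)
        dh = dlogits @ self.dense[3].W.T
        layer_grads = [(gW3, gb3, None, None)]
        for li in (2, 1, 0):
            c = cache[li]
            da = dh * (c["a"] > 0)
            bn = self.bn[li]
            ggamma = (da * c["zhat"]).sum(axis=0)
            gbeta = da.sum(axis=0)
            # batch-norm backward (batch statistics)
            m = da.shape[0]
            dzhat = da * bn.gamma
            dz = (
                c["inv_std"]
                / m
                * (m * dzhat - dzhat.sum(axis=0) - c["zhat"] * (dzhat * c["zhat"]).sum(axis=0))
            )
            gW = c["h"].T @ dz
            gb = dz.sum(axis=0)
            dh = dz @ self.dense[li].W.T
            layer_grads.append((gW, gb, ggamma, gbeta))
        layer_grads.reverse()
        flat: list[np.ndarray] = []
        for gW, gb, _, _ in layer_grads:
            flat.extend((gW, gb))
        for _, _, ggamma, gbeta in layer_grads[:3]:
            flat.extend((ggamma, gbeta))
        return flat

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(np.atleast_2d(X), training=False)
        return probs

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(_LAYER_SIZES),
            "dense": [{"W": d.W.tolist(), "b": d.b.tolist()} for d in self.dense],
            "bn": [
                {
                    "gamma": bn.gamma.tolist(),
                    "beta": bn.beta.tolist(),
                    "running_mean": bn.running_mean.tolist(),
                    "running_var": bn.running_var.tolist(),
                }
                for bn in self.bn
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PoseClassifier":
        model = cls(seed=0)
        for d, src in zip(model.dense, data["dense"]):
            d.W = np.asarray(src["W"])
            d.b = np.asarray(src["b"])
        for bn, src in zip(model.bn, data["bn"]):
            bn.gamma = np.asarray(src["gamma"])
            bn.beta = np.asarray(src["beta"])
            bn.running_mean = np.asarray(src["running_mean"])
            bn.running_var = np.asarray(src["running_var"])
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PoseClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_classifier(seed: int = 0) -> PoseClassifier:
    """Construct the pose network with deterministic initialization."""
    return PoseClassifier(seed=seed)


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


def train_classifier(
    model: PoseClassifier,
    features: np.ndarray,
    labels: np.ndarray,
    epochs: int = 30,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> TrainingHistory:
    """Minimize cross-entropy with Adam over shuffled mini-batches.

    ``features`` is (n, 32); ``labels`` integer class indices.  Requires
    at least two distinct classes.  Returns per-epoch mean loss and
    training accuracy; the model is updated in place.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[1] != FEATURE_DIM:
        raise ValueError(f"features must be (n, {FEATURE_DIM})")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("training needs at least two classes")
    rng = np.random.default_rng(seed)
    params = self_params = model.parameters()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = TrainingHistory()
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if len(idx) < 2:
                continue  # batch norm needs at least 2 samples
            probs, cache = model.forward(X[idx], training=True)
            losses.append(float(-np.mean(np.log(probs[np.arange(len(idx)), y[idx]] + 1e-12))))
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
            grads = model.backward(probs, cache, y[idx])
            t += 1
            for p, g, mi, vi in zip(self_params, grads, m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g * g
                mhat = mi / (1 - beta1**t)
                vhat = vi / (1 - beta2**t)
                p -= learning_rate * mhat / (np.sqrt(vhat) + eps)
        history.loss.append(float(np.mean(losses)))
        history.accuracy.append(correct / n)
    return history


def classify(model: PoseClassifier, skel: CowSkeleton, normalize: bool = True) -> PoseProbabilities:
    """Class probabilities and argmax label for one skeleton."""
    feat = featurize(skel, normalize=normalize)
    probs = model.predict_proba(feat.values[None, :])[0]
    return PoseProbabilities(probs)
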