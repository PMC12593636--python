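"""Dual-view slice-pooled ordinal classifier (multiple-instance, late fusion).

One lobe sample is a pair of 2D slice stacks (coronal + axial) with a single
ordinal label 0/1/2.  Each slice runs through a 2D convolutional backbone;
adaptive average pooling turns each slice's feature map into a descriptor;
max pooling over the slice dimension collapses the stack to one descriptor
per view (only the strongest slice evidence survives — the multiple-instance
step that lets lobe-level labels supervise slice-level features); the two
view descriptors are concatenated (late fusion) and a linear head predicts
the three classes.  Training is plain SGD with a step learning-rate
schedule, class-weighted cross-entropy, online rotation/flip augmentation
and early stopping on validation loss.

The backbone is a contract: anything mapping a (S, 3, H, W) slice batch to
(S, C, h, w) feature maps with a matching backward pass can stand in.  The
default :class:`TinyBackbone` is a small three-block CNN that trains on a
CPU; a large ImageNet-pretrained backbone can be plugged in behind the same
contract (weights are not shipped).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn import Conv2d, Linear, MaxPool2d, ReLU, Sequential
from .preprocess import LobeSample

__all__ = [
    "TinyBackbone",
    "TrainConfig",
    "PredictionRecord",
    "DualViewLobeClassifier",
    "slice_features",
    "pool_slices",
    "fuse_and_classify",
    "class_weights",
    "weighted_loss",
    "augment",
]


class TinyBackbone:
    """Three-block CNN slice-feature extractor (conv3x3-ReLU[-pool] x3).

    Satisfies the backbone contract: ``forward`` maps (S, 3, H, W) to
    (S, C, H/4, W/4) feature maps, ``feature_channels`` is the constant
    output channel count, and the module is deterministic in inference.
    """

    def __init__(self, channels: tuple[int, int, int] = (8, 16, 32),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        c1, c2, c3 = channels
        self.net = Sequential(
            Conv2d(3, c1, rng), ReLU(), MaxPool2d(),
            Conv2d(c1, c2, rng), ReLU(), MaxPool2d(),
            Conv2d(c2, c3, rng), ReLU(),
        )
        self.feature_channels = c3

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)

    def params(self):
        return self.net.params()

    def zero_grad(self):
        self.net.zero_grad()

    def sgd_step(self, lr: float):
        self.net.sgd_step(lr)


@dataclass
class TrainConfig:
    """Optimisation schedule (defaults follow the full-scale protocol:
    SGD, initial LR 1e-5 decayed by gamma 0.4 every 15 epochs, at most 125
    epochs, early stopping after 25 epochs without validation improvement).
    Scaled-down phantom experiments override lr/max_epochs."""

    lr: float = 1e-5
    scheduler_gamma: float = 0.4
    scheduler_step: int = 15
    max_epochs: int = 125
    early_stop_patience: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.scheduler_gamma, self.scheduler_step,
               self.max_epochs, self.early_stop_patience) <= 0:
            raise ValueError("all training parameters must be positive")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate in effect during ``epoch`` (0-based)."""
        return self.lr * self.scheduler_gamma ** (epoch // self.scheduler_step)


@dataclass
class PredictionRecord:
    """Per-lobe class probabilities and the derived ordinal prediction."""

    patient_id: str
    exam_id: str
    lobe_id: int
    pathology: str
    probabilities: np.ndarray
    predicted_score: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1) > 1e-6:
            raise ValueError("probabilities must be a 3-vector summing to 1")
        if self.predicted_score != int(np.argmax(p)):
            raise ValueError("predicted_score must be the argmax class (lowest index on ties)")


def _to_channels(stack: np.ndarray) -> np.ndarray:
    """Repeat single-channel slices to the 3-channel backbone input."""
    return np.repeat(stack[:, None, :, :], 3, axis=1)


def slice_features(stack: np.ndarray, backbone) -> np.ndarray:
    """Per-slice feature descriptors: backbone map -> spatial average.

    Returns an (S, C) array whose row order matches the slice order.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be (S>=1, H, W)")
    feat = backbone.forward(_to_channels(stack))
    return feat.mean(axis=(2, 3))


def pool_slices(descriptors: np.ndarray) -> np.ndarray:
    """Elementwise maximum over the slice dimension: (S, C) -> (C,)."""
    descriptors = np.asarray(descriptors)
    if descriptors.ndim != 2 or descriptors.shape[0] < 1:
        raise ValueError("descriptors must be (S>=1, C)")
    return descriptors.max(axis=0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def fuse_and_classify(
    coronal_desc: np.ndarray, axial_desc: np.ndarray, head: Linear
) -> tuple[np.ndarray, np.ndarray]:
    """Late fusion: concatenate view descriptors, apply the linear head."""
    coronal_desc = np.asarray(coronal_desc).ravel()
    axial_desc = np.asarray(axial_desc).ravel()
    if coronal_desc.shape != axial_desc.shape:
        raise ValueError("view descriptors must have equal length")
    if head.W.shape[1] != 2 * coronal_desc.size:
        raise ValueError(
            f"head expects {head.W.shape[1]} inputs, got {2 * coronal_desc.size}"
        )
    logits = head.forward(np.concatenate([coronal_desc, axial_desc]))
    return logits, _softmax(logits)


def class_weights(label_counts, invert: bool = False) -> np.ndarray:
    """Loss weights from class counts, normalised to mean 1.

    Default is inverse frequency (rare classes weighted up), the standard
    imbalance treatment.  ``invert=True`` weights classes proportionally to
    their frequency instead (majority classes penalised more) for
    faithfulness experiments.  Zero-count classes receive the max (resp.
    min) of the defined weights.
    """
    counts = np.asarray(label_counts, dtype=float)
    if counts.shape != (3,) or np.any(counts < 0):
        raise ValueError("label_counts must be 3 nonnegative numbers")
    if counts.sum() == 0:
        raise ValueError("at least one class count must be nonzero")
    nz = counts > 0
    w = np.empty(3)
    if invert:
        w[nz] = counts[nz] * 3 / counts.sum()
        w[~nz] = w[nz].min() if (~nz).any() else 0
    else:
        w[nz] = counts.sum() / (3 * counts[nz])
        w[~nz] = w[nz].max() if (~nz).any() else 0
    return w / w.mean()


def weighted_loss(
    logits: np.ndarray, label: int, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted cross-entropy and its gradient w.r.t. the logits."""
    if label not in (0, 1, 2):
        raise ValueError(f"label must be 0, 1 or 2, got {label}")
    p = _softmax(np.asarray(logits, dtype=float))
    loss = -weights[label] * np.log(max(p[label], 1e-300))
    grad = weights[label] * p
    grad[label] -= weights[label]
    return float(loss), grad


def _rotate_stack(stack: np.ndarray, angle: float) -> np.ndarray:
    if angle == 0.0:
        return stack
    out = ndimage.rotate(stack, angle, axes=(1, 2), reshape=False, order=1,
                         mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


def _augment_view(stack: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    angle = rng.uniform(-180.0, 180.0)
    flip_h = rng.random() < 0.5
    flip_v = rng.random() < 0.5
    out = _rotate_stack(stack, angle)
    if flip_h:
        out = out[:, :, ::-1]
    if flip_v:
        out = out[:, ::-1, :]
    return np.ascontiguousarray(out)


def augment(
    coronal_stack: np.ndarray, axial_stack: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Online augmentation: per view, a uniform rotation in (-180, 180)
    degrees applied to every slice consistently, then horizontal/vertical
    flips with probability 0.5 each.  Draws are independent per view."""
    return _augment_view(coronal_stack, rng), _augment_view(axial_stack, rng)


class DualViewLobeClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style estimator over :class:`LobeSample` inputs.

    ``X`` is a sequence of :class:`LobeSample`; ``y`` defaults to the
    samples' own labels.  A validation set (patient-disjoint from the
    training samples) is required by ``fit`` for early stopping, matching
    the training protocol.

    Parameters
    ----------
    backbone_channels : tuple of 3 ints
        Channel widths of the tiny backbone; the last entry is the
        descriptor length D per view.
    lr, scheduler_gamma, scheduler_step, max_epochs, early_stop_patience
        SGD schedule; see :class:`TrainConfig`.
    momentum : float
        Classical SGD momentum (0 disables it).
    class_weight : {"inverse", "proportional", None}
        Loss weighting. "inverse" up-weights rare classes (default);
        "proportional" penalises majority classes more.
    augment : bool
        Online rotation/flip augmentation during training.
    seed : int
        Controls weight initialisation, sample order and augmentation.
    """

    def __init__(
        self,
        backbone_channels: tuple[int, int, int] = (8, 16, 32),
        lr: float = 1e-5,
        scheduler_gamma: float = 0.4,
        scheduler_step: int = 15,
        max_epochs: int = 125,
        early_stop_patience: int = 25,
        momentum: float = 0.9,
        class_weight: str | None = "inverse",
        augment: bool = True,
        seed: int = 0,
    ):
        self.backbone_channels = backbone_channels
        self.lr = lr
        self.scheduler_gamma = scheduler_gamma
        self.scheduler_step = scheduler_step
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.momentum = momentum
        self.class_weight = class_weight
        self.augment = augment
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _forward_sample(self, cor: np.ndarray, ax: np.ndarray):
        caches = {}
        descs = []
        for view, stack, backbone in (
            ("coronal", cor, self.backbones_["coronal"]),
            ("axial", ax, self.backbones_["axial"]),
        ):
            feat = backbone.forward(_to_channels(stack))
            desc = feat.mean(axis=(2, 3))  # (S, C)
            pooled = desc.max(axis=0)
            caches[view] = {
                "feat": feat,
                "argmax": desc.argmax(axis=0),
                "shape": feat.shape,
            }
            descs.append(pooled)
        fused = np.concatenate(descs)
        logits = self.head_.forward(fused)
        return logits, caches

    def _backward_sample(self, dlogits: np.ndarray, caches) -> None:
        dfused = self.head_.backward(dlogits)
        c = self.backbones_["coronal"].feature_channels
        for view, dview in (("coronal", dfused[:c]), ("axial", dfused[c:])):
            cache = caches[view]
            s, ch, h, w = cache["shape"]
            ddesc = np.zeros((s, ch))
            ddesc[cache["argmax"], np.arange(ch)] = dview
            dfeat = np.broadcast_to(
                ddesc[:, :, None, None] / (h * w), cache["shape"]
            ).copy()
            self.backbones_[view].backward(dfeat)

    def _zero_grad(self) -> None:
        self.backbones_["coronal"].zero_grad()
        self.backbones_["axial"].zero_grad()
        for _, g in self.head_.params():
            g[...] = 0.0

    def _all_params(self):
        return (
            self.backbones_["coronal"].params()
            + self.backbones_["axial"].params()
            + self.head_.params()
        )

    def _step(self, lr: float) -> None:
        params = self._all_params()
        if self._velocities is None:
            self._velocities = [np.zeros_like(p) for p, _ in params]
        for (p, g), v in zip(params, self._velocities):
            v *= self.momentum
            v -= lr * g
            p += v

    def _snapshot(self):
        return copy.deepcopy(
            {"coronal": self.backbones_["coronal"], "axial": self.backbones_["axial"],
             "head": self.head_}
        )

    def _restore(self, state) -> None:
        self.backbones_ = {"coronal": state["coronal"], "axial": state["axial"]}
        self.head_ = state["head"]

    def _mean_loss(self, X, y) -> float:
        total = 0.0
        for sample, label in zip(X, y):
            logits, _ = self._forward_sample(sample.coronal_stack, sample.axial_stack)
            loss, _ = weighted_loss(logits, int(label), self.class_weights_)
            total += loss
        return total / len(X)

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None, X_val=None, y_val=None):
        """Train with SGD + step LR schedule + early stopping.

        ``X_val`` must be non-empty and patient-disjoint from ``X``.
        """
        X = list(X)
        if y is None:
            y = [s.label for s in X]
        y = np.asarray(y, dtype=int)
        if X_val is None or len(X_val) == 0:
            raise ValueError("fit requires a non-empty validation set (X_val)")
        X_val = list(X_val)
        if y_val is None:
            y_val = [s.label for s in X_val]
        y_val = np.asarray(y_val, dtype=int)
        train_patients = {s.patient_id for s in X}
        leaked = train_patients & {s.patient_id for s in X_val}
        if leaked:
            raise ValueError(f"patients appear in both train and validation: {sorted(leaked)[:5]}")

        rng = np.random.default_rng(self.seed)
        self.backbones_ = {
            "coronal": TinyBackbone(self.backbone_channels, rng),
            "axial": TinyBackbone(self.backbone_channels, rng),
        }
        d = self.backbones_["coronal"].feature_channels
        self.head_ = Linear(2 * d, 3, rng)
        self.classes_ = np.array([0, 1, 2])
        self._velocities = None

        counts = np.bincount(y, minlength=3)[:3].astype(float)
        if self.class_weight == "inverse":
            self.class_weights_ = class_weights(counts)
        elif self.class_weight == "inverse_sqrt":
            # tempered reweighting: up-weights rare classes by the square
            # root of the inverse frequency, trading some rare-class recall
            # for fewer severe over-calls on the common classes
            w = np.where(counts > 0, 1.0 / np.sqrt(np.maximum(counts, 1)), 0.0)
            if (counts == 0).any() and w.max() > 0:
                w[counts == 0] = w[w > 0].max()
            self.class_weights_ = w / w.mean()
        elif self.class_weight == "proportional":
            self.class_weights_ = class_weights(counts, invert=True)
        elif self.class_weight is None:
            self.class_weights_ = np.ones(3)
        else:
            raise ValueError(f"unknown class_weight {self.class_weight!r}")

        cfg = TrainConfig(
            lr=self.lr, scheduler_gamma=self.scheduler_gamma,
            scheduler_step=self.scheduler_step, max_epochs=self.max_epochs,
            early_stop_patience=self.early_stop_patience, seed=self.seed,
        )
        history = []
        best_val = np.inf
        best_state = None
        stale = 0
        for epoch in range(cfg.max_epochs):
            lr = cfg.lr_at_epoch(epoch)
            order = rng.permutation(len(X))
            train_loss = 0.0
            for i in order:
                sample, label = X[i], int(y[i])
                cor, ax = sample.coronal_stack, sample.axial_stack
                if self.augment:
                    cor, ax = augment(cor, ax, rng)
                logits, caches = self._forward_sample(cor, ax)
                loss, dlogits = weighted_loss(logits, label, self.class_weights_)
                self._zero_grad()
                self._backward_sample(dlogits, caches)
                self._step(lr)
                train_loss += loss
            val_loss = self._mean_loss(X_val, y_val)
            history.append(
                {"epoch": epoch, "train_loss": train_loss / len(X),
                 "val_loss": val_loss, "lr": lr}
            )
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = self._snapshot()
                stale = 0
            else:
                stale += 1
                if stale >= cfg.early_stop_patience:
                    break
        if best_state is not None:
            self._restore(best_state)
        self.history_ = pd.DataFrame(history)
        self.best_val_loss_ = float(best_val)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "head_"):
            raise ValueError("classifier is not fitted")
        out = np.empty((len(X), 3))
        for i, sample in enumerate(X):
            logits, _ = self._forward_sample(sample.coronal_stack, sample.axial_stack)
            out[i] = _softmax(logits)
        return out

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def predict_records(self, X) -> list[PredictionRecord]:
        """Per-lobe prediction records (probabilities + argmax score)."""
        probs = self.predict_proba(X)
        return [
            PredictionRecord(
                patient_id=s.patient_id, exam_id=s.exam_id, lobe_id=s.lobe_id,
                pathology=s.pathology, probabilities=p, predicted_score=int(p.argmax()),
            )
            for s, p in zip(X, probs)
        ]


def predict_lobe(model: DualViewLobeClassifier, sample: LobeSample) -> PredictionRecord:
    """Deterministic single-lobe prediction (argmax, lowest index on ties)."""
    return model.predict_records([sample])[0]
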