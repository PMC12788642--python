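"""Reference CNN and repeated stratified k-fold evaluation.

The classifier is a small convolutional network operating on the
grayscale pseudo-images: two blocks of (3x3 convolution, stride 1, same
padding -> batch normalization -> ReLU -> 2x2 max pooling) with 32 and 64
filters, a 64-unit dense head with dropout 0.25, and a sigmoid output
trained with binary cross-entropy and Adam.  Training monitors a held-out
validation split: the learning rate is halved after 5 epochs without
validation-loss improvement, and training stops early after 10 such
epochs, restoring the best weights.

The network is implemented directly in NumPy (im2col convolutions over
BLAS matmuls, float32 throughout) and is fully deterministic for a given
seed and thread configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold, train_test_split

from .io import PseudoImageSet

__all__ = ["CNNSpec", "Indices", "CVReport", "compute_indices", "train_once", "cross_validate"]


@dataclass
class CNNSpec:
    """Hyperparameters of the reference CNN (defaults fixed for reproducibility)."""

    filters: tuple[int, int] = (32, 64)
    dense_units: int = 64
    dropout: float = 0.25
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 100
    lr_factor: float = 0.5
    lr_patience: int = 5
    es_patience: int = 10
    es_min_delta: float = 1e-3
    val_fraction: float = 0.1
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(self.filters) != 2:
            raise ValueError("exactly two convolutional blocks are required")
        if self.lr_patience < 1 or self.es_patience < 1:
            raise ValueError("patience values must be >= 1")


# ---------------------------------------------------------------- layers

def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches for a 3x3 same-padded conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3)
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
    return np.ascontiguousarray(col, dtype=np.float32)


class _Conv3x3:
    """3x3 convolution, stride 1, same (zero) padding.

    ``first=True`` marks the input layer, whose input gradient is never
    needed and is skipped in the backward pass.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, first: bool = False):
        fan_in = c_in * 9
        self.W = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out
        self.first = first

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = (n, c, h, w)
        self._col = _im2col(x)
        out = self._col @ self.W + self.b
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray):
        n, c, h, w = self._shape
        dcol = np.ascontiguousarray(
            dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        )
        dW = self._col.T @ dcol
        db = dcol.sum(axis=0)
        if self.first:
            return None, [dW, db]
        # dx: full correlation of dout with spatially flipped kernels
        Wk = self.W.reshape(self.c_in, 3, 3, self.c_out)
        Wrot = Wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(self.c_out * 9, self.c_in)
        dout_col = _im2col(dout.astype(np.float32))
        dx = (dout_col @ Wrot).reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)
        return dx, [dW, db]


class _BatchNorm:
    """Per-channel batch normalization with running inference statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        ax = (0, 2, 3)
        sh = (1, -1, 1, 1)
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        self._cache = (xhat, inv)
        return self.gamma.reshape(sh) * xhat + self.beta.reshape(sh)

    def backward(self, dout: np.ndarray):
        xhat, inv = self._cache
        ax = (0, 2, 3)
        sh = (1, -1, 1, 1)
        dgamma = (dout * xhat).sum(axis=ax)
        dbeta = dout.sum(axis=ax)
        dxhat = dout * self.gamma.reshape(sh)
        dx = (
            dxhat - dxhat.mean(axis=ax).reshape(sh) - xhat * (dxhat * xhat).mean(axis=ax).reshape(sh)
        ) * inv.reshape(sh)
        return dx, [dgamma, dbeta]


class _ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray):
        return dout * self._mask, []


class _MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        hp, wp = h // 2, w // 2
        self._in_shape = (n, c, h, w)
        self._slices = [
            x[:, :, i : hp * 2 : 2, j : wp * 2 : 2] for i in (0, 1) for j in (0, 1)
        ]
        out = np.maximum(
            np.maximum(self._slices[0], self._slices[1]),
            np.maximum(self._slices[2], self._slices[3]),
        )
        self._out = out
        return out

    def backward(self, dout: np.ndarray):
        n, c, h, w = self._in_shape
        hp, wp = h // 2, w // 2
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        remaining = np.ones_like(dout, dtype=bool)
        views = [
            dx[:, :, i : hp * 2 : 2, j : wp * 2 : 2] for i in (0, 1) for j in (0, 1)
        ]
        # route gradient to the first window cell attaining the max
        for sl, view in zip(self._slices, views):
            hit = remaining & (sl == self._out)
            view += dout * hit
            remaining &= ~hit
        return dx, []


class _Flatten:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray):
        return dout.reshape(self._shape), []


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray):
        return dout @ self.W.T, [self._x.T @ dout, dout.sum(axis=0)]


class _ReLU1D(_ReLU):
    pass


class _Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self._rng = rate, rng

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray):
        if self._mask is None:
            return dout, []
        return dout * self._mask, []


class SmallCNN:
    """The two-block reference network; see module docstring."""

    def __init__(self, grid_shape: tuple[int, int], spec: CNNSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        f1, f2 = spec.filters
        h, w = grid_shape
        h2, w2 = (h // 2) // 2, (w // 2) // 2
        self.spec = spec
        self.layers = [
            _Conv3x3(1, f1, rng, first=True), _BatchNorm(f1), _ReLU(), _MaxPool2(),
            _Conv3x3(f1, f2, rng), _BatchNorm(f2), _ReLU(), _MaxPool2(),
            _Flatten(),
            _Dense(f2 * h2 * w2, spec.dense_units, rng), _ReLU1D(),
            _Dropout(spec.dropout, rng),
            _Dense(spec.dense_units, 1, rng),
        ]
        self._rng = rng

    # -- parameter plumbing -------------------------------------------
    def _param_refs(self):
        return [p for layer in self.layers for p in layer.params()]

    def get_weights(self):
        return [p.copy() for p in self._param_refs()] + [
            (la.run_mean.copy(), la.run_var.copy())
            for la in self.layers
            if isinstance(la, _BatchNorm)
        ]

    def set_weights(self, weights) -> None:
        refs = self._param_refs()
        for ref, val in zip(refs, weights[: len(refs)]):
            ref[...] = val
        bns = [la for la in self.layers if isinstance(la, _BatchNorm)]
        for la, (rm, rv) in zip(bns, weights[len(refs):]):
            la.run_mean, la.run_var = rm.copy(), rv.copy()

    # -- forward / backward -------------------------------------------
    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return out[:, 0]  # logits

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class-1 probability for a stack of (n, H, W) images."""
        x = np.asarray(images, dtype=np.float32)[:, None, :, :]
        outs = []
        for s in range(0, x.shape[0], batch_size):
            logits = self._forward(x[s : s + batch_size], train=False)
            outs.append(expit(logits))
        return np.concatenate(outs)

    def _train_batch(self, x: np.ndarray, y: np.ndarray, opt: "_Adam") -> float:
        logits = self._forward(x, train=True)
        prob = expit(logits)
        eps = 1e-7
        loss = -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
        dlogits = ((prob - y) / x.shape[0]).astype(np.float32)[:, None]
        grads: list[np.ndarray] = []
        d = dlogits
        for layer in reversed(self.layers):
            d, g = layer.backward(d)
            grads = g + grads
        opt.step(self._param_refs(), grads)
        return float(loss)

    def eval_loss(self, images: np.ndarray, y: np.ndarray, batch_size: int = 64) -> float:
        prob = self.predict_proba(images, batch_size=batch_size)
        eps = 1e-7
        return float(-np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g = g.astype(p.dtype)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------- training

def train_once(
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    spec: CNNSpec | None = None,
    seed: int = 0,
) -> SmallCNN:
    """Train the reference CNN with LR reduction and early stopping.

    Returns the fitted model with the best-validation-loss weights
    restored.  Raises if the training fold contains a single class.
    """
    spec = spec or CNNSpec()
    train_labels = np.asarray(train_labels)
    val_labels = np.asarray(val_labels)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training fold has a single class; use stratified splits")
    x = np.asarray(train_images, dtype=np.float32)[:, None, :, :]
    y = train_labels.astype(np.float32)
    model = SmallCNN(train_images.shape[1:], spec, seed=seed)
    opt = _Adam(spec.learning_rate)
    rng = np.random.default_rng(seed + 1)

    best_loss = np.inf
    best_weights = model.get_weights()
    since_best = 0
    model.epochs_run = 0
    for _epoch in range(spec.max_epochs):
        model.epochs_run = _epoch + 1
        order = rng.permutation(x.shape[0])
        for s in range(0, x.shape[0], spec.batch_size):
            idx = order[s : s + spec.batch_size]
            model._train_batch(x[idx], y[idx], opt)
        vloss = model.eval_loss(val_images, val_labels)
        if vloss < best_loss - spec.es_min_delta:
            best_loss = vloss
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best == spec.lr_patience:
                opt.lr *= spec.lr_factor
            if since_best >= spec.es_patience:
                break
    model.set_weights(best_weights)
    return model


# ---------------------------------------------------------------- metrics

@dataclass
class Indices:
    """Accuracy / precision / recall / F1 from one confusion table."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()

    def __iter__(self):
        return iter((self.accuracy, self.precision, self.recall, self.f1))


def compute_indices(tp: int, fp: int, tn: int, fn: int) -> Indices:
    """Validation indices from confusion counts; undefined ratios -> 0, flagged."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be nonnegative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion table")
    undefined = []
    accuracy = (tp + tn) / total
    if tp + fp == 0:
        precision, und = 0.0, True
        undefined.append("precision")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        undefined.append("recall")
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
        if "precision" not in undefined or "recall" not in undefined:
            undefined.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Indices(accuracy, precision, recall, f1, tuple(undefined))


INDEX_NAMES = ("accuracy", "precision", "recall", "f1")


@dataclass
class CVReport:
    """Per-fold confusion counts and indices with mean/sd aggregates."""

    folds: int
    repeats: int
    seed: int
    counts: list[dict[str, int]] = field(default_factory=list)
    indices: list[Indices] = field(default_factory=list)

    def values(self, name: str) -> np.ndarray:
        if name not in INDEX_NAMES:
            raise KeyError(name)
        return np.array([getattr(ix, name) for ix in self.indices])

    def mean(self, name: str) -> float:
        return float(self.values(name).mean())

    def sd(self, name: str) -> float:
        return float(self.values(name).std(ddof=0))

    def cell(self, name: str) -> str:
        """Table-style "mean (sd)" string, e.g. ``0.8700 (0.0557)``."""
        return f"{self.mean(name):.4f} ({self.sd(name):.4f})"

    def summary(self) -> dict[str, Any]:
        return {
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
            **{
                name: {"mean": self.mean(name), "sd": self.sd(name), "cell": self.cell(name)}
                for name in INDEX_NAMES
            },
        }


def cross_validate(
    imgs: PseudoImageSet,
    spec: CNNSpec | None = None,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold CV of the reference CNN.

    For each repeat x fold the model trains on the other k-1 folds (with a
    stratified 10% inner validation split feeding the LR-reduction and
    early-stopping callbacks) and is scored on the held-out fold at
    threshold 0.5.  The images must already be built; the layout never
    sees the labels, so no target information leaks into the transform.
    """
    spec = spec or CNNSpec()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = imgs.y
    counts_per_class = np.bincount(y, minlength=2)
    if counts_per_class.min() < folds:
        raise ValueError("every class needs at least `folds` members for stratification")
    X = imgs.images
    report = CVReport(folds=folds, repeats=repeats, seed=seed)
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + 1000 * rep)
        for fold_i, (tr, te) in enumerate(skf.split(X, y)):
            fold_seed = seed + 1000 * rep + fold_i
            tr_in, tr_val = train_test_split(
                tr,
                test_size=spec.val_fraction,
                stratify=y[tr],
                random_state=fold_seed,
            )
            model = train_once(
                X[tr_in], y[tr_in], X[tr_val], y[tr_val], spec, seed=fold_seed
            )
            prob = model.predict_proba(X[te])
            pred = (prob >= spec.threshold).astype(int)
            truth = y[te]
            tp = int(((pred == 1) & (truth == 1)).sum())
            fp = int(((pred == 1) & (truth == 0)).sum())
            tn = int(((pred == 0) & (truth == 0)).sum())
            fn = int(((pred == 0) & (truth == 1)).sum())
            report.counts.append({"tp": tp, "fp": fp, "tn": tn, "fn": fn})
            report.indices.append(compute_indices(tp, fp, tn, fn))
    return report
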