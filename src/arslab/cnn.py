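"""Compact convolutional neural networks on time-frequency images.

A small, self-contained numpy implementation (im2col convolutions, 2x2 max
pooling, dense head, Adam, categorical cross-entropy) supporting single- and
dual-input configurations: each input branch stacks convolution blocks
(convolution -> rectifier -> max-pool), the branch outputs are flattened and
concatenated, and a dense layer feeds a softmax over the classes.  The
default architecture uses three blocks with 16/32/64 filters of size 3x3 and
a 64-unit dense layer; it is configurable, and all experiment conclusions
are behavioral rather than tied to one architecture.

Training follows the protocol: up to 30 epochs, batch size 16, learning
rate 0.001 with adaptive-moment (Adam) updates, and early stopping once the
validation loss has not improved for 10 consecutive epochs, restoring the
best-validation-loss parameters.  Everything is deterministic given the
seed, which controls initialization, the train/validation split and batch
shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ValidationError


# ------------------------------ layers ------------------------------------

class _Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, g):
        raise NotImplementedError


class Conv2D(_Layer):
    """3x3-style valid convolution via im2col."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator):
        fan_in = in_ch * ksize * ksize
        self.W = rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(out_ch)
        self.ksize = ksize
        self.in_ch = in_ch
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        # x: (N, C, H, W)
        k = self.ksize
        cols = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,Ho,Wo,k,k)
        n, c, ho, wo = cols.shape[:4]
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        self._cols = cols
        self._shape = (n, ho, wo, x.shape)
        out = cols @ self.W.T + self.b
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, g):
        n, ho, wo, x_shape = self._shape
        g2 = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, -1)
        self.grads[0][...] = g2.T @ self._cols
        self.grads[1][...] = g2.sum(axis=0)
        gcols = g2 @ self.W  # (n*ho*wo, C*k*k)
        k = self.ksize
        gx = np.zeros(x_shape)
        gcols = gcols.reshape(n, ho, wo, self.in_ch, k, k)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di : di + ho, dj : dj + wo] += gcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return gx


class ReLU(_Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2(_Layer):
    """2x2 max pooling with stride 2 (trailing odd row/column dropped)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, :, : h2 * 2, : w2 * 2]
        self._xshape = (n, c, h, w)
        blocks = x.reshape(n, c, h2, 2, w2, 2)
        out = blocks.max(axis=(3, 5))
        self._argmask = blocks == out[:, :, :, None, :, None]
        return out

    def backward(self, g):
        n, c, h, w = self._xshape
        h2, w2 = h // 2, w // 2
        gx = np.zeros((n, c, h, w))
        spread = self._argmask * g[:, :, :, None, :, None]
        gx[:, :, : h2 * 2, : w2 * 2] = spread.reshape(n, c, h2 * 2, w2 * 2)
        return gx


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


# ------------------------------ model -------------------------------------

@dataclass(frozen=True)
class CNNSpec:
    """Architecture description.

    ``branch_shapes`` lists one (channels, time, frequency) input shape per
    branch: a single entry builds a single-input network, two entries the
    dual-input configuration (spectrogram + mel spectrogram).
    """

    branch_shapes: tuple[tuple[int, int, int], ...]
    n_classes: int
    conv_filters: tuple[int, ...] = (16, 32, 64)
    ksize: int = 3
    dense_units: int = 64

    def __post_init__(self):
        if len(self.branch_shapes) < 1:
            raise ValidationError("need at least one input branch")
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")


@dataclass(frozen=True)
class TrainProtocol:
    """Training settings: epoch budget, batching, Adam step size, early
    stopping patience on validation loss, validation fraction, seed."""

    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 0.001
    patience: int = 10
    val_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.val_fraction < 1):
            raise ValidationError("val_fraction must be in (0, 1)")
        if self.patience >= self.epochs:
            raise ValidationError("patience must be smaller than the epoch budget")


class CNNModel:
    """Single- or dual-branch convolutional classifier."""

    def __init__(self, spec: CNNSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.branches: list[list[_Layer]] = []
        flat_total = 0
        for shape in spec.branch_shapes:
            c, h, w = shape
            layers: list[_Layer] = []
            for out_ch in spec.conv_filters:
                if h < spec.ksize or w < spec.ksize:
                    raise ValidationError(
                        f"input {shape} too small for {len(spec.conv_filters)} conv blocks"
                    )
                layers.append(Conv2D(c, out_ch, spec.ksize, rng))
                h, w = h - spec.ksize + 1, w - spec.ksize + 1
                layers.append(ReLU())
                layers.append(MaxPool2())
                h, w = h // 2, w // 2
                c = out_ch
                if h < 1 or w < 1:
                    raise ValidationError(f"input {shape} collapses before the dense head")
            self.branches.append(layers)
            flat_total += c * h * w
        self.head: list[_Layer] = [
            Dense(flat_total, spec.dense_units, rng),
            ReLU(),
            Dense(spec.dense_units, spec.n_classes, rng),
        ]
        self.classes_: np.ndarray | None = None

    # -- plumbing ----------------------------------------------------------
    def _all_layers(self):
        for branch in self.branches:
            yield from branch
        yield from self.head

    def parameters(self):
        for layer in self._all_layers():
            yield from zip(layer.params, layer.grads)

    def n_parameters(self) -> int:
        return sum(p.size for layer in self._all_layers() for p in layer.params)

    def get_weights(self):
        return [p.copy() for layer in self._all_layers() for p in layer.params]

    def set_weights(self, weights):
        i = 0
        for layer in self._all_layers():
            for p in layer.params:
                p[...] = weights[i]
                i += 1

    # -- forward/backward --------------------------------------------------
    def _check_inputs(self, inputs: list[np.ndarray]):
        if len(inputs) != len(self.spec.branch_shapes):
            raise ValidationError(
                f"model expects {len(self.spec.branch_shapes)} inputs, got {len(inputs)}"
            )
        for x, shape in zip(inputs, self.spec.branch_shapes):
            if tuple(x.shape[1:]) != tuple(shape):
                raise ValidationError(f"input shape {x.shape[1:]} != spec {shape}")

    def forward(self, inputs: list[np.ndarray], train=False) -> np.ndarray:
        self._check_inputs(inputs)
        flats = []
        self._flat_shapes = []
        for x, layers in zip(inputs, self.branches):
            h = np.asarray(x, dtype=np.float64)
            for layer in layers:
                h = layer.forward(h, train=train)
            self._flat_shapes.append(h.shape)
            flats.append(h.reshape(h.shape[0], -1))
        h = np.concatenate(flats, axis=1)
        self._split_sizes = [f.shape[1] for f in flats]
        for layer in self.head:
            h = layer.forward(h, train=train)
        # softmax
        z = h - h.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def backward(self, grad_logits: np.ndarray):
        g = grad_logits
        for layer in reversed(self.head):
            g = layer.backward(g)
        offset = 0
        for layers, size, shape in zip(self.branches, self._split_sizes, self._flat_shapes):
            gb = g[:, offset : offset + size].reshape(shape)
            offset += size
            for layer in reversed(layers):
                gb = layer.backward(gb)


def build_cnn(spec: CNNSpec, seed: int = 0) -> CNNModel:
    """Construct an untrained network; parameter count is available via
    ``model.n_parameters()`` for logging."""
    return CNNModel(spec, seed)


class _Adam:
    def __init__(self, model: CNNModel, lr: float):
        self.model = model
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in model.parameters()]
        self.v = [np.zeros_like(p) for p, _ in model.parameters()]

    def step(self):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(self.model.parameters()):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mh = self.m[i] / (1 - b1**self.t)
            vh = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


def _cross_entropy(proba: np.ndarray, y_idx: np.ndarray) -> float:
    return float(-np.mean(np.log(proba[np.arange(y_idx.size), y_idx] + 1e-12)))


def train_cnn(
    model: CNNModel,
    images: list[np.ndarray],
    labels: np.ndarray,
    protocol: TrainProtocol = TrainProtocol(),
) -> dict:
    """Train in place; returns a history dict with per-epoch losses.

    ``images`` is a list with one (N, C, H, W) array per input branch.
    Training stops after ``patience`` consecutive epochs without a new best
    validation loss, and the best-validation parameters are restored.
    """
    labels = np.asarray(labels)
    classes, y_idx = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValidationError("single-class training data")
    n = labels.size
    if n <= protocol.batch_size:
        raise ValidationError("dataset must be larger than one batch")
    model.classes_ = classes
    if classes.size != model.spec.n_classes:
        raise ValidationError(
            f"model has {model.spec.n_classes} outputs but data has {classes.size} classes"
        )
    rng = np.random.default_rng(protocol.seed)

    # stratified validation split
    val_idx: list[int] = []
    for c in range(classes.size):
        members = np.nonzero(y_idx == c)[0]
        members = members[rng.permutation(members.size)]
        n_val = max(1, int(round(protocol.val_fraction * members.size)))
        val_idx.extend(members[:n_val])
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    tr = np.nonzero(~val_mask)[0]
    va = np.nonzero(val_mask)[0]

    Xtr = [x[tr] for x in images]
    Xva = [x[va] for x in images]
    ytr, yva = y_idx[tr], y_idx[va]

    opt = _Adam(model, protocol.learning_rate)
    history = {"train_loss": [], "val_loss": [], "val_acc": [], "stopped_epoch": None}
    best_loss, best_weights, best_epoch = np.inf, model.get_weights(), 0
    streak = 0
    for epoch in range(1, protocol.epochs + 1):
        order = rng.permutation(tr.size)
        losses = []
        for start in range(0, tr.size, protocol.batch_size):
            batch = order[start : start + protocol.batch_size]
            xb = [x[batch] for x in Xtr]
            yb = ytr[batch]
            proba = model.forward(xb, train=True)
            losses.append(_cross_entropy(proba, yb))
            grad = proba.copy()
            grad[np.arange(yb.size), yb] -= 1.0
            model.backward(grad / yb.size)
            opt.step()
        proba_val = model.forward(Xva)
        val_loss = _cross_entropy(proba_val, yva)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(float(np.mean(np.argmax(proba_val, axis=1) == yva)))
        if val_loss < best_loss - 1e-12:
            best_loss, best_weights, best_epoch = val_loss, model.get_weights(), epoch
            streak = 0
        else:
            streak += 1
            if streak >= protocol.patience:
                history["stopped_epoch"] = epoch
                break
    model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    return history


def predict_cnn(model: CNNModel, images: list[np.ndarray]):
    """Labels and class probabilities; ties broken toward the lowest class index."""
    if any(x.shape[0] == 0 for x in images):
        k = model.spec.n_classes
        return np.empty(0, dtype=object), np.empty((0, k))
    proba = model.forward(images)
    idx = np.argmax(proba, axis=1)
    labels = model.classes_[idx] if model.classes_ is not None else idx
    return labels, proba


__all__ = ["CNNSpec", "TrainProtocol", "CNNModel", "build_cnn", "train_cnn", "predict_cnn"]
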