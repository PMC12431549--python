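"""Minimal numpy realization of the declarative CNN specs.

A :class:`Model` is built from an :class:`~ecglite.architecture.ModelSpec`
and supports exactly what the pipeline needs: seeded Glorot initialization,
mini-batch training with categorical cross-entropy and Adam, batched
probability prediction, and access to intermediate conv activations and
their class-score gradients (for Grad-CAM).  Convolutions are im2col
matmuls.  Arithmetic is single precision by default (pass
``dtype=np.float64`` for gradient checking) and fully deterministic given
the seed, so two runs with identical seed and data produce identical
weights and predictions.

Layout convention: batches are (n, length, channels); conv weights are
(kernel, in_channels, filters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .architecture import LayerDescriptor, ModelSpec

_EPS = 1e-12


class _Layer:
    """Base class: stateless unless it carries weights."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _Conv1D(_Layer):
    """Same-padded stride-1 1D convolution with optional ReLU."""

    def __init__(self, ld: LayerDescriptor, in_channels: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        k, f = ld.kernel_size, ld.filters
        fan_in, fan_out = k * in_channels, k * f
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, size=(k, in_channels, f)).astype(dtype)
        self.b = np.zeros(f, dtype=dtype)
        self.relu = ld.activation == "relu"
        self.k, self.cin, self.f = k, in_channels, f
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training, rng):
        n, L, _ = x.shape
        k = self.k
        left = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (left, k - 1 - left), (0, 0)))
        # (n, L, cin, k) -> (n, L, k, cin)
        cols = sliding_window_view(xp, k, axis=1).transpose(0, 1, 3, 2)
        self._cols = cols.reshape(n * L, k * self.cin)
        y = (self._cols @ self.W.reshape(k * self.cin, self.f)).reshape(n, L, self.f)
        y += self.b
        if self.relu:
            self._mask = y > 0
            y = np.where(self._mask, y, 0.0)
        self._in_shape = (n, L)
        return y

    def backward(self, dy):
        n, L = self._in_shape
        k = self.k
        if self.relu:
            dy = dy * self._mask
        dy_flat = dy.reshape(n * L, self.f)
        self.grads[0][...] = (self._cols.T @ dy_flat).reshape(k, self.cin, self.f)
        self.grads[1][...] = dy_flat.sum(axis=0)
        # gradient w.r.t. input: full correlation of dy with the flipped kernel
        dyp = np.pad(dy, ((0, 0), (k - 1, k - 1), (0, 0)))
        cols2 = sliding_window_view(dyp, k, axis=1).transpose(0, 1, 3, 2)
        W_flip = self.W[::-1].transpose(0, 2, 1).reshape(k * self.f, self.cin)
        dxp = (cols2.reshape(-1, k * self.f) @ W_flip).reshape(n, L + k - 1, self.cin)
        left = (k - 1) // 2
        return dxp[:, left:left + L, :]


class _MaxPool1D(_Layer):
    def __init__(self, ld: LayerDescriptor):
        super().__init__()
        self.pool, self.stride = ld.pool_size, ld.stride

    def forward(self, x, training, rng):
        self._in_shape = x.shape
        win = sliding_window_view(x, self.pool, axis=1)[:, ::self.stride]
        self._argmax = win.argmax(axis=-1)  # (n, Lout, C)
        return win.max(axis=-1)

    def backward(self, dy):
        n, L, C = self._in_shape
        lout = dy.shape[1]
        dx = np.zeros((n, L, C), dtype=dy.dtype)
        ni, ti, ci = np.meshgrid(np.arange(n), np.arange(lout), np.arange(C),
                                 indexing="ij")
        pos = ti * self.stride + self._argmax
        np.add.at(dx, (ni, pos, ci), dy)
        return dx


class _Flatten(_Layer):
    def forward(self, x, training, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class _Dropout(_Layer):
    def __init__(self, ld: LayerDescriptor):
        super().__init__()
        self.rate = ld.rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class _Dense(_Layer):
    def __init__(self, ld: LayerDescriptor, in_features: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        limit = np.sqrt(6.0 / (in_features + ld.units))
        self.W = rng.uniform(-limit, limit, size=(in_features, ld.units)).astype(dtype)
        self.b = np.zeros(ld.units, dtype=dtype)
        self.relu = ld.activation == "relu"
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training, rng):
        self._x = x
        y = x @ self.W + self.b
        if self.relu:
            self._mask = y > 0
            y = np.where(self._mask, y, 0.0)
        return y

    def backward(self, dy):
        if self.relu:
            dy = dy * self._mask
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class _Softmax(_Layer):
    def forward(self, x, training, rng):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def backward(self, dy):
        # only used fused with cross-entropy; the trainer hands in d(logits)
        raise RuntimeError("softmax backward is fused with the cross-entropy loss")


@dataclass
class TrainHistory:
    """Per-epoch training loss and accuracy."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


class Model:
    """A realized sequential CNN with training and introspection hooks."""

    def __init__(self, spec: ModelSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.layers: list[_Layer] = []
        length, channels = spec.input_len, spec.input_channels
        flat = False
        for ld in spec.layers:
            if ld.kind == "conv1d":
                self.layers.append(_Conv1D(ld, channels, rng, self.dtype))
                channels = ld.filters
            elif ld.kind == "maxpool1d":
                self.layers.append(_MaxPool1D(ld))
                length = (length - ld.pool_size) // ld.stride + 1
            elif ld.kind == "flatten":
                self.layers.append(_Flatten())
                length, channels, flat = length * channels, 1, True
            elif ld.kind == "dropout":
                self.layers.append(_Dropout(ld))
            elif ld.kind == "dense":
                if not flat:
                    raise ValueError("dense layer before flatten is not supported")
                self.layers.append(_Dense(ld, length, rng, self.dtype))
                length = ld.units
            elif ld.kind == "softmax":
                self.layers.append(_Softmax())
        self._dropout_rng = np.random.default_rng(seed + 1)

    # ------------------------------------------------------------------ util

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = [p for layer in self.layers for p in layer.params]
        if len(weights) != len(params):
            raise ValueError(f"expected {len(params)} weight arrays, got {len(weights)}")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w.astype(p.dtype)

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] != self.spec.input_len or x.shape[2] != self.spec.input_channels:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match spec "
                f"({self.spec.input_len}, {self.spec.input_channels})"
            )
        return x

    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, self._dropout_rng)
        return x

    def predict_proba(self, windows: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Class probabilities, rows summing to 1."""
        x = self._check_input(windows)
        out = [self._forward(x[i:i + batch_size], training=False)
               for i in range(0, len(x), batch_size)]
        probs = np.concatenate(out, axis=0).astype(np.float64)
        return probs / probs.sum(axis=1, keepdims=True)

    # -------------------------------------------------------------- training

    def fit(self, windows: np.ndarray, labels_onehot: np.ndarray,
            epochs: int = 50, batch_size: int = 32, learning_rate: float = 0.001,
            seed: int = 0) -> TrainHistory:
        """Mini-batch Adam on categorical cross-entropy; fully seeded."""
        x = self._check_input(windows)
        y = np.asarray(labels_onehot, dtype=self.dtype)
        if y.shape != (len(x), self.spec.n_classes):
            raise ValueError(
                f"labels shape {y.shape} does not match ({len(x)}, {self.spec.n_classes})"
            )
        if self.layers and not isinstance(self.layers[-1], _Softmax):
            raise ValueError("training requires a terminal softmax layer")
        shuffle_rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)

        params = [p for layer in self.layers for p in layer.params]
        grads = [g for layer in self.layers for g in layer.grads]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-7
        t = 0
        history = TrainHistory()
        for _epoch in range(epochs):
            order = shuffle_rng.permutation(len(x))
            losses, correct = [], 0
            for start in range(0, len(x), batch_size):
                idx = order[start:start + batch_size]
                xb, yb = x[idx], y[idx]
                probs = self._forward(xb, training=True)
                losses.append(float(-np.mean(np.sum(yb * np.log(probs + _EPS), axis=1))))
                correct += int(np.sum(probs.argmax(axis=1) == yb.argmax(axis=1)))
                dy = (probs - yb) / len(xb)  # fused softmax + cross-entropy
                for layer in reversed(self.layers[:-1]):
                    dy = layer.backward(dy)
                t += 1
                lr_t = float(learning_rate * np.sqrt(1 - b2 ** t) / (1 - b1 ** t))
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= b1
                    mi += (1 - b1) * g
                    vi *= b2
                    vi += (1 - b2) * g * g
                    p -= lr_t * mi / (np.sqrt(vi) + eps)
            history.loss.append(float(np.mean(losses)))
            history.accuracy.append(correct / len(x))
        return history

    # ----------------------------------------------------------- grad access

    def conv_layer_indices(self) -> list[int]:
        return [i for i, layer in enumerate(self.layers) if isinstance(layer, _Conv1D)]

    def activations_and_gradients(self, window: np.ndarray, class_index: int,
                                  layer_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Conv activations A (L, K) and d(logit_c)/dA for one window.

        The class score is the pre-softmax logit; dropout is inactive.
        """
        if not isinstance(self.layers[layer_index], _Conv1D):
            raise ValueError(f"layer {layer_index} is not a conv layer")
        x = self._check_input(np.atleast_2d(np.asarray(window)))
        if len(x) != 1:
            raise ValueError("one window at a time")
        h = x
        acts: np.ndarray | None = None
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, False, self._dropout_rng)
            if i == layer_index:
                acts = h.copy()
        assert acts is not None
        logits_layer = len(self.layers) - 1
        if isinstance(self.layers[-1], _Softmax):
            logits_layer -= 1
        n_classes = self.spec.n_classes
        if not 0 <= class_index < n_classes:
            raise ValueError(f"class index {class_index} out of range")
        dy = np.zeros((1, n_classes), dtype=self.dtype)
        dy[0, class_index] = 1.0
        for layer in reversed(self.layers[layer_index + 1:logits_layer + 1]):
            dy = layer.backward(dy)
        return acts[0], dy[0]
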