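"""A compact 3-D spectral CNN engine (forward, backprop, SGD) in numpy.

The networks used here are small (~32k trainable parameters) and operate on
``l x w x w`` spectral sub-volumes with batch-size-1 SGD, so a direct
im2col/matmul implementation is fast enough and keeps every numerical step
inspectable.

Architecture description is declarative: a :class:`CNNSpec` lists layers
(3-D convolutions, ReLUs, a fully connected head); parameter counts and the
shape trace are derived from the spec in closed form and must agree with
runtime introspection of a built network.

Convention: feature maps are ``(batch, channels, z, x, y)`` with ``z`` the
spectral axis.  "Pooling" layers are trainable 1-D spectral convolutions with
stride 2 in z (strided convs, not max pooling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# Declarative architecture spec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerSpec:
    """One layer: ``conv3d`` (kernel/stride/spectral padding/out channels),
    ``relu``, or the ``fc`` head (out channels = number of outputs)."""

    kind: str  # "conv3d" | "relu" | "fc"
    name: str = ""
    kernel: tuple[int, int, int] = (1, 1, 1)  # (z, x, y)
    stride: tuple[int, int, int] = (1, 1, 1)
    spectral_pad: int = 0
    out_channels: int = 0


@dataclass(frozen=True)
class CNNSpec:
    """Ordered layer list plus the expected input shape ``(l, w, w)``."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = (100, 5, 5)

    @property
    def n_outputs(self) -> int:
        return self.layers[-1].out_channels


def spectral_cnn_spec(n_outputs: int, l: int = 100, w: int = 5) -> CNNSpec:
    """The damage/peak-temperature network architecture.

    Three 3-D conv blocks with progressively larger spectral receptive
    fields; the intermediate "pooling" layers are trainable 1-D spectral
    convolutions with stride 2.  Spectral padding is 1 on all six feature
    layers; spatial padding is zero, so a 5x5 spatial window collapses to
    1x1 after two (3,3,3) convolutions.  The head is a single FC layer with
    *n_outputs* neurons (3 for the damage segmenter, 1 for the peak
    temperature regressor).
    """
    conv = lambda name, k, s, c: LayerSpec(  # noqa: E731
        "conv3d", name, kernel=k, stride=s, spectral_pad=1, out_channels=c
    )
    layers = (
        conv("Conv1", (3, 3, 3), (1, 1, 1), 20),
        LayerSpec("relu", "ReLU1"),
        conv("Pool1", (3, 1, 1), (2, 1, 1), 20),
        conv("Conv2", (3, 3, 3), (1, 1, 1), 35),
        LayerSpec("relu", "ReLU2"),
        conv("Pool2", (3, 1, 1), (2, 1, 1), 35),
        conv("Conv3", (3, 1, 1), (1, 1, 1), 35),
        LayerSpec("relu", "ReLU3"),
        conv("Pool3", (2, 1, 1), (2, 1, 1), 35),
        LayerSpec("relu", "ReLU4"),
        LayerSpec("fc", "FC", out_channels=n_outputs),
    )
    return CNNSpec(layers, input_shape=(l, w, w))


def _conv_out(size: int, kernel: int, stride: int, pad: int) -> int:
    out = (size + 2 * pad - kernel) // stride + 1
    if out < 1:
        raise ValueError(
            f"layer output collapses: size={size}, kernel={kernel}, "
            f"stride={stride}, pad={pad}"
        )
    return out


def shape_trace(spec: CNNSpec) -> list[tuple[str, tuple[int, int, int, int]]]:
    """Propagate ``(1, l, w, w)`` through the spec; returns
    ``[(layer name, (channels, z, x, y)), ...]`` including the input."""
    c, (z, x, y) = 1, spec.input_shape
    trace = [("input", (c, z, x, y))]
    for layer in spec.layers:
        if layer.kind == "conv3d":
            kz, kx, ky = layer.kernel
            sz, sx, sy = layer.stride
            z = _conv_out(z, kz, sz, layer.spectral_pad)
            x = _conv_out(x, kx, sx, 0)
            y = _conv_out(y, ky, sy, 0)
            c = layer.out_channels
        elif layer.kind == "fc":
            c, z, x, y = layer.out_channels, 1, 1, 1
        trace.append((layer.name or layer.kind, (c, z, x, y)))
    return trace


def flattened_size(spec: CNNSpec) -> int:
    """Length of the flattened feature vector entering the FC head."""
    trace = shape_trace(spec)
    fc_pos = next(i for i, l in enumerate(spec.layers) if l.kind == "fc")
    return int(np.prod(trace[fc_pos][1]))  # trace[i] is the shape *before* layer i+...


def count_parameters(spec_or_model, per_layer: bool = False):
    """Closed-form trainable-parameter counts (weights + biases).

    ``conv3d``: ``kz*kx*ky*C_in*C_out + C_out``; ``fc``: ``n_in*n_out + n_out``.
    Accepts a :class:`CNNSpec` or a built :class:`SpectralCNN` (for the
    latter, counts are taken by introspection of the actual arrays).
    """
    if isinstance(spec_or_model, SpectralCNN):
        counts = {
            layer.spec.name or layer.spec.kind: layer.weight.size + layer.bias.size
            for layer in spec_or_model.layers
            if isinstance(layer, (_Conv3d, _Linear))
        }
    else:
        spec: CNNSpec = spec_or_model
        counts = {}
        c_in = 1
        for layer in spec.layers:
            if layer.kind == "conv3d":
                kz, kx, ky = layer.kernel
                counts[layer.name] = kz * kx * ky * c_in * layer.out_channels + layer.out_channels
                c_in = layer.out_channels
            elif layer.kind == "fc":
                n_in = flattened_size(spec)
                counts[layer.name] = n_in * layer.out_channels + layer.out_channels
    total = int(sum(counts.values()))
    return ({k: int(v) for k, v in counts.items()}, total) if per_layer else total


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class _Conv3d:
    """3-D convolution via precomputed-unfold gather + matmul.

    The gather index is built once per input shape; the backward pass folds
    the column gradient back with ``np.bincount`` over the same index, which
    is exact and fast at these sizes.
    """

    def __init__(self, spec: LayerSpec, in_channels: int, rng: np.random.Generator):
        self.spec = spec
        self.in_channels = in_channels
        kz, kx, ky = spec.kernel
        fan_in = kz * kx * ky * in_channels
        self.weight = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(spec.out_channels, fan_in)
        )
        self.bias = np.zeros(spec.out_channels)
        self._idx_cache: dict[tuple, tuple] = {}

    def _indices(self, in_shape: tuple[int, int, int]):
        key = in_shape
        if key not in self._idx_cache:
            z, x, y = in_shape
            kz, kx, ky = self.spec.kernel
            sz, sx, sy = self.spec.stride
            pz = self.spec.spectral_pad
            zp = z + 2 * pz
            zo = (zp - kz) // sz + 1
            xo = (x - kx) // sx + 1
            yo = (y - ky) // sy + 1
            c = self.in_channels
            # flat index into padded (c, zp, x, y)
            ci, zi, xi, yi = np.meshgrid(
                np.arange(c), np.arange(kz), np.arange(kx), np.arange(ky),
                indexing="ij",
            )
            base = ((ci * zp + zi) * x + xi) * y + yi  # (c, kz, kx, ky)
            zs, xs, ys = np.meshgrid(
                np.arange(zo) * sz, np.arange(xo) * sx, np.arange(yo) * sy,
                indexing="ij",
            )
            offs = (zs * x + xs) * y + ys  # (zo, xo, yo)
            idx = offs.reshape(-1, 1) + base.reshape(1, -1)  # (P, K)
            self._idx_cache[key] = (idx, (zo, xo, yo), zp)
        return self._idx_cache[key]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, z, xd, yd = x.shape
        idx, out_sp, zp = self._indices((z, xd, yd))
        pz = self.spec.spectral_pad
        if pz:
            xpad = np.zeros((n, c, zp, xd, yd), dtype=x.dtype)
            xpad[:, :, pz:-pz] = x
        else:
            xpad = x
        cols = xpad.reshape(n, -1)[:, idx]  # (n, P, K)
        out = cols @ self.weight.T + self.bias  # (n, P, Cout)
        if train:
            self._cols = cols
            self._in_shape = (z, xd, yd)
        zo, xo, yo = out_sp
        return out.transpose(0, 2, 1).reshape(n, self.spec.out_channels, zo, xo, yo)

    def backward(self, dout: np.ndarray):
        n = dout.shape[0]
        z, xd, yd = self._in_shape
        idx, out_sp, zp = self._indices((z, xd, yd))
        pz = self.spec.spectral_pad
        c_out = self.spec.out_channels
        dy = dout.reshape(n, c_out, -1).transpose(0, 2, 1)  # (n, P, Cout)
        cols = self._cols
        k = cols.shape[2]
        dy2 = np.ascontiguousarray(dy).reshape(-1, c_out)
        self.dweight = dy2.T @ cols.reshape(-1, k)
        self.dbias = dy2.sum(axis=0)
        dcols = dy @ self.weight  # (n, P, K)
        flat_len = self.in_channels * zp * xd * yd
        dxpad = np.empty((n, flat_len))
        rav = idx.ravel()
        for i in range(n):  # training batch is 1; loop cost negligible
            dxpad[i] = np.bincount(rav, weights=dcols[i].ravel(), minlength=flat_len)
        dxpad = dxpad.reshape(n, self.in_channels, zp, xd, yd)
        self._cols = None
        return dxpad[:, :, pz : zp - pz] if pz else dxpad

    def sgd_step(self, lr: float) -> None:
        self.weight -= lr * self.dweight
        self.bias -= lr * self.dbias


class _ReLU:
    spec = LayerSpec("relu")

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask

    def sgd_step(self, lr):
        pass


class _Linear:
    def __init__(self, spec: LayerSpec, n_in: int, rng: np.random.Generator):
        self.spec = spec
        self.weight = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(spec.out_channels, n_in))
        self.bias = np.zeros(spec.out_channels)

    def forward(self, x, train=False):
        n = x.shape[0]
        flat = x.reshape(n, -1)
        if train:
            self._x = flat
            self._in_shape = x.shape
        return flat @ self.weight.T + self.bias

    def backward(self, dout):
        self.dweight = dout.T @ self._x
        self.dbias = dout.sum(axis=0)
        dx = dout @ self.weight
        shape = self._in_shape
        self._x = None
        return dx.reshape(shape)

    def sgd_step(self, lr):
        self.weight -= lr * self.dweight
        self.bias -= lr * self.dbias


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class SpectralCNN:
    """A built network: ordered layers with shared forward/backward/SGD."""

    def __init__(self, spec: CNNSpec, rng: np.random.Generator | int | None = 0):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.spec = spec
        self.layers = []
        c_in = 1
        for lspec in spec.layers:
            if lspec.kind == "conv3d":
                self.layers.append(_Conv3d(lspec, c_in, rng))
                c_in = lspec.out_channels
            elif lspec.kind == "relu":
                self.layers.append(_ReLU())
            elif lspec.kind == "fc":
                self.layers.append(_Linear(lspec, flattened_size(spec), rng))
            else:
                raise ValueError(f"unknown layer kind {lspec.kind!r}")

    @property
    def n_parameters(self) -> int:
        return count_parameters(self)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """*x*: ``(n, l, w, w)`` or ``(n, 1, l, w, w)``; returns ``(n, n_outputs)``."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 4:
            x = x[:, None]
        l, w, _ = self.spec.input_shape
        if x.shape[2:] != (l, w, w):
            raise ValueError(f"input shape {x.shape[2:]} != expected {(l, w, w)}")
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def sgd_step(self, lr: float) -> None:
        for layer in self.layers:
            layer.sgd_step(lr)

    # -- flat parameter archive (checkpoint support) --
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, (_Conv3d, _Linear)):
                name = layer.spec.name or f"layer{i}"
                out[f"{name}.weight"] = layer.weight
                out[f"{name}.bias"] = layer.bias
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            if isinstance(layer, (_Conv3d, _Linear)):
                name = layer.spec.name or f"layer{i}"
                layer.weight = np.asarray(state[f"{name}.weight"], dtype=np.float64)
                layer.bias = np.asarray(state[f"{name}.bias"], dtype=np.float64)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def inverse_frequency_weights(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Class weights ``w_c`` proportional to 1/frequency, normalised so that
    ``sum_c w_c = n_classes`` (uniform frequencies give all-ones)."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    present = counts > 0
    if not present.any():
        raise ValueError("no labels given")
    inv = np.zeros(n_classes)
    inv[present] = 1.0 / counts[present]
    return inv * (n_classes / inv.sum())


def weighted_cross_entropy(
    logits: np.ndarray, label: int, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Inverse-frequency weighted softmax cross-entropy for one sample.

    Returns ``(loss, dloss/dlogits)``.
    """
    logits = np.asarray(logits, dtype=np.float64).ravel()
    n_classes = logits.size
    if not (0 <= label < n_classes):
        raise ValueError(f"label {label} outside 0..{n_classes - 1}")
    w = np.asarray(class_weights, dtype=np.float64)
    if np.any(w < 0) or w[label] <= 0:
        # absent classes may carry zero weight; the observed label may not
        raise ValueError("class weight for an observed label must be positive")
    z = logits - logits.max()
    p = np.exp(z)
    p /= p.sum()
    loss = -w[label] * np.log(max(p[label], 1e-300))
    grad = w[label] * p
    grad[label] -= w[label]
    return float(loss), grad


def mean_relative_error(
    pred: np.ndarray, actual: np.ndarray, eps: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean relative error ``mean(|pred - actual| / actual)`` and its
    gradient w.r.t. *pred*.  Targets below *eps* (1 degC) are rejected: the
    loss is ill-conditioned there and valid tissue is never that cold."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    actual = np.asarray(actual, dtype=np.float64).ravel()
    if np.any(actual < eps):
        raise ValueError(f"target below {eps} degC; relative error undefined")
    err = (pred - actual) / actual
    loss = float(np.mean(np.abs(err)))
    grad = np.sign(err) / actual / err.size
    return loss, grad
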