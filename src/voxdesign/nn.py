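"""A compact 3D convolutional network engine in numpy.

Implements exactly the layer vocabulary the residue classifiers need —
3D convolution, ELU, spatial (channel) dropout, max pooling, global average
pooling, flatten, dense — with hand-written backward passes and an Adam
optimiser.  Tensors are channels-last: ``(batch, D, H, W, C)``.

Convolutions use an im2col formulation: patch gathers are precomputed as a
flat index table per input shape, so the forward pass is a single matrix
multiply and the input gradient a single ``bincount`` scatter-add.  This is
deliberately simple and fully deterministic under a fixed seed, which the
training contract relies on.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "Layer", "Conv3D", "ELU", "SpatialDropout3D", "MaxPool3D",
    "GlobalAveragePooling3D", "Flatten", "Dense", "Sequential",
    "Adam", "softmax", "softmax_cross_entropy",
]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and the gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Layer:
    """Base layer: ``params`` and ``grads`` are parallel name->array dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3D(Layer):
    """3D convolution, stride 1, 'same' or 'valid' padding."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int = 3,
                 padding: str = "same", rng: np.random.Generator | None = None):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        self.in_channels = in_channels
        self.filters = filters
        self.kernel_size = kernel_size
        self.padding = padding
        k3c = kernel_size ** 3 * in_channels
        rng = rng or np.random.default_rng()
        # He initialisation, suited to ELU/ReLU-family activations
        self.params["w"] = rng.normal(0.0, np.sqrt(2.0 / k3c),
                                      size=(k3c, filters))
        self.params["b"] = np.zeros(filters)
        self._cache_shape = None
        self._idx = None

    def _prepare(self, spatial: tuple[int, int, int]) -> None:
        if self._cache_shape == spatial:
            return
        k, c = self.kernel_size, self.in_channels
        pad = (k - 1) // 2 if self.padding == "same" else 0
        dp, hp, wp = (s + 2 * pad for s in spatial)
        do, ho, wo = ((s + 2 * pad - k + 1) for s in spatial)
        d0, h0, w0 = np.meshgrid(np.arange(do), np.arange(ho), np.arange(wo),
                                 indexing="ij")
        start = (((d0 * hp) + h0) * wp + w0) * c  # flat index of patch origin
        kd, kh, kw, kc = np.meshgrid(np.arange(k), np.arange(k), np.arange(k),
                                     np.arange(c), indexing="ij")
        offsets = (((kd * hp) + kh) * wp + kw) * c + kc
        self._idx = (start.reshape(-1, 1)
                     + offsets.reshape(1, -1)).astype(np.intp)
        self._pad = pad
        self._padded = (dp, hp, wp)
        self._out_spatial = (do, ho, wo)
        self._cache_shape = spatial

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b = x.shape[0]
        self._prepare(x.shape[1:4])
        if self._pad:
            p = self._pad
            x = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        xf = x.reshape(b, -1)
        cols = xf[:, self._idx]  # (B, P, k^3*C)
        out = cols @ self.params["w"] + self.params["b"]
        if training:
            self._cols = cols
        return out.reshape(b, *self._out_spatial, self.filters)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b = grad.shape[0]
        g = grad.reshape(b, -1, self.filters)  # (B, P, F)
        cols = self._cols
        self.grads["w"] = np.einsum("bpk,bpf->kf", cols, g)
        self.grads["b"] = g.sum(axis=(0, 1))
        dcols = g @ self.params["w"].T  # (B, P, K)
        dp, hp, wp = self._padded
        npad = dp * hp * wp * self.in_channels
        flat = (np.arange(b)[:, None, None] * npad + self._idx[None]).ravel()
        dxf = np.bincount(flat, weights=dcols.ravel(),
                          minlength=b * npad)
        dx = dxf.reshape(b, dp, hp, wp, self.in_channels)
        if self._pad:
            p = self._pad
            dx = dx[:, p:-p, p:-p, p:-p, :]
        self._cols = None
        return dx


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False):
        out = np.where(x > 0, x, self.alpha * np.expm1(x))
        if training:
            self._out = out
            self._pos = x > 0
        return out

    def backward(self, grad):
        return grad * np.where(self._pos, 1.0, self._out + self.alpha)


class SpatialDropout3D(Layer):
    """Drops entire feature channels, preserving spatial coherence."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random((x.shape[0], 1, 1, 1, x.shape[-1])) < keep)
        self._mask = mask / keep
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool3D(Layer):
    """Non-overlapping max pooling; trailing voxels beyond a full window drop."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False):
        p = self.pool
        b, d, h, w, c = x.shape
        do, ho, wo = d // p, h // p, w // p
        xt = x[:, :do * p, :ho * p, :wo * p, :].reshape(
            b, do, p, ho, p, wo, p, c)
        out = xt.max(axis=(2, 4, 6))
        if training:
            self._x_shape = x.shape
            self._xt = xt
            self._out = out
        return out

    def backward(self, grad):
        p = self.pool
        b, do, ho, wo, c = grad.shape
        mask = self._xt == self._out[:, :, None, :, None, :, None, :]
        g = grad[:, :, None, :, None, :, None, :] * mask
        # spread ties equally so the gradient of the max is well defined
        g = g / np.maximum(mask.sum(axis=(2, 4, 6), keepdims=True), 1)
        dx = np.zeros(self._x_shape)
        dx[:, :do * p, :ho * p, :wo * p, :] = g.reshape(
            b, do * p, ho * p, wo * p, c)
        return dx


class GlobalAveragePooling3D(Layer):
    def forward(self, x, training=False):
        self._spatial = x.shape[1:4]
        return x.mean(axis=(1, 2, 3))

    def backward(self, grad):
        d, h, w = self._spatial
        scale = 1.0 / (d * h * w)
        return np.broadcast_to(
            grad[:, None, None, None, :] * scale,
            (grad.shape[0], d, h, w, grad.shape[-1])).copy()


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["w"] = rng.normal(0.0, np.sqrt(2.0 / in_features),
                                      size=(in_features, out_features))
        self.params["b"] = np.zeros(out_features)

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad):
        self.grads["w"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        dx = grad @ self.params["w"].T
        self._x = None
        return dx


class DenseBlock3D(Layer):
    """DenseNet-style block: each conv sees the concatenation of all earlier
    feature maps and contributes ``growth_rate`` new channels."""

    def __init__(self, in_channels: int, n_layers: int, growth_rate: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.convs: list[Conv3D] = []
        self.elus: list[ELU] = []
        ch = in_channels
        for _ in range(n_layers):
            self.convs.append(Conv3D(ch, growth_rate, 3, "same", rng=rng))
            self.elus.append(ELU())
            ch += growth_rate
        self.out_channels = ch
        for i, conv in enumerate(self.convs):
            for name, p in conv.params.items():
                self.params[f"conv{i}_{name}"] = p

    def _sync_param_views(self):
        # optimiser updates self.params in place; keep conv views aligned
        for i, conv in enumerate(self.convs):
            for name in conv.params:
                conv.params[name] = self.params[f"conv{i}_{name}"]

    def forward(self, x, training=False):
        self._sync_param_views()
        feats = x
        self._widths = [x.shape[-1]]
        for conv, elu in zip(self.convs, self.elus):
            y = elu.forward(conv.forward(feats, training), training)
            feats = np.concatenate([feats, y], axis=-1)
            self._widths.append(y.shape[-1])
        return feats

    def backward(self, grad):
        cuts = np.cumsum(self._widths)[:-1]
        parts = np.split(grad, cuts, axis=-1)
        acc = list(parts[:-1])
        gy = parts[-1]
        for i in range(len(self.convs) - 1, -1, -1):
            gx = self.convs[i].backward(self.elus[i].backward(gy))
            for name in self.convs[i].grads:
                self.grads[f"conv{i}_{name}"] = self.convs[i].grads[name]
            sub_cuts = np.cumsum(self._widths[:i + 1])[:-1]
            sub = np.split(gx, sub_cuts, axis=-1)
            for j in range(len(sub)):
                acc[j] = acc[j] + sub[j]
            if i > 0:
                gy = acc.pop()
        return acc[0]


class Sequential:
    """A feed-forward stack producing class logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers
                for name in layer.params]

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"layer{i}_{name}": layer.params[name]
                for i, layer in enumerate(self.layers)
                for name in layer.params}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                key = f"layer{i}_{name}"
                if layer.params[name].shape != arrays[key].shape:
                    raise ValueError(f"shape mismatch for {key}")
                layer.params[name] = arrays[key].copy()


class Adam:
    """Adam optimiser over a :class:`Sequential`'s parameters."""

    def __init__(self, net: Sequential, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {id(l): {n: np.zeros_like(p) for n, p in l.params.items()}
                  for l in net.layers}
        self.v = {id(l): {n: np.zeros_like(p) for n, p in l.params.items()}
                  for l in net.layers}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name in self.net.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self.m[id(layer)][name]
            v = self.v[id(layer)][name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def save_net(net: Sequential, path: str | Path, meta: dict | None = None) -> None:
    """Persist weights as .npz with a JSON sidecar of metadata."""
    path = Path(path)
    np.savez(path, **net.state_arrays())
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_net_arrays(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(Path(path)) as data:
        return {k: data[k] for k in data.files}
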