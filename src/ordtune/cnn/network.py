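"""Hierarchical convolutional network, implemented in NumPy.

Eight convolutional blocks (convolution with "same" padding, batch
normalization, ReLU), max-pooling after the first five blocks, adaptive
average pooling, and a 1,000-way linear classification head:

    block  maps  spatial (conv output)  kernel
      1      32      224 x 224           9 x 9   -> pool -> 112
      2      48      112 x 112           9 x 9   -> pool ->  56
      3      96       56 x  56           7 x 7   -> pool ->  28
      4     192       28 x  28           5 x 5   -> pool ->  14
      5     384       14 x  14           5 x 5   -> pool ->   7
      6     768        7 x   7           5 x 5
      7     768        7 x   7           5 x 5
      8     768        7 x   7           5 x 5

The unit-selectivity analysis reads the post-ReLU activation of the last
convolutional block: 768 x 7 x 7 = 37,632 units.  This is an
inference-oriented implementation (batch norm runs in inference mode from
stored statistics); weights are randomly initialized unless a checkpoint
is loaded, and the full analysis pipeline is weight-agnostic.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ArchitectureSpec",
    "OrdinalityCNN",
    "build_architecture",
    "CheckpointError",
    "N_ANALYSIS_UNITS",
]

#: Units in the default analysis layer (768 feature maps of 7 x 7).
N_ANALYSIS_UNITS = 768 * 7 * 7


class CheckpointError(RuntimeError):
    """Checkpoint does not match the architecture; lists offending layers."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer plan of the eight-block network."""

    channels: tuple = (32, 48, 96, 192, 384, 768, 768, 768)
    kernels: tuple = (9, 9, 7, 5, 5, 5, 5, 5)
    n_pooled_blocks: int = 5
    n_classes: int = 1000
    input_size: int = 224
    analysis_layer: str = "relu8"

    def conv_spatial_sizes(self) -> list:
        """Spatial size of each block's convolution output."""
        sizes, s = [], self.input_size
        for i in range(len(self.channels)):
            sizes.append(s)
            if i < self.n_pooled_blocks:
                s //= 2
        return sizes

    def layer_shapes(self) -> "OrderedDict[str, tuple]":
        """Analytic (channels, height, width) after every named layer."""
        shapes = OrderedDict()
        s = self.input_size
        for i, c in enumerate(self.channels, start=1):
            shapes[f"conv{i}"] = (c, s, s)
            shapes[f"bn{i}"] = (c, s, s)
            shapes[f"relu{i}"] = (c, s, s)
            if i <= self.n_pooled_blocks:
                s //= 2
                shapes[f"pool{i}"] = (c, s, s)
        shapes["avgpool"] = (self.channels[-1], 1, 1)
        shapes["fc"] = (self.n_classes,)
        return shapes


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, pad: int) -> np.ndarray:
    """Same-padding convolution; x (N,C,H,W), w (O,C,k,k) -> (N,O,H,W)."""
    k = w.shape[-1]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    out = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))  # (N,H,W,O)
    out = np.moveaxis(out, -1, 1)
    return (out + b[None, :, None, None]).astype(np.float32)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x[:, :, : h // 2 * 2, : w // 2 * 2].reshape(
        n, c, h // 2, 2, w // 2, 2
    ).max(axis=(3, 5))


class _Conv:
    def __init__(self, c_in, c_out, k, rng):
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_out, c_in, k, k)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.pad = k // 2

    def __call__(self, x):
        return _conv2d(x, self.W, self.b, self.pad)

    def params(self):
        return {"W": self.W, "b": self.b}


class _BatchNorm:
    """Inference-mode batch normalization from stored statistics."""

    eps = 1e-5

    def __init__(self, c):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.mean = np.zeros(c, dtype=np.float32)
        self.var = np.ones(c, dtype=np.float32)

    def __call__(self, x):
        scale = self.gamma / np.sqrt(self.var + self.eps)
        shift = self.beta - self.mean * scale
        return x * scale[None, :, None, None] + shift[None, :, None, None]

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta,
                "mean": self.mean, "var": self.var}


class _Linear:
    def __init__(self, n_in, n_out, rng):
        self.W = (rng.standard_normal((n_out, n_in)) *
                  np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def __call__(self, x):
        return x @ self.W.T + self.b

    def params(self):
        return {"W": self.W, "b": self.b}


class OrdinalityCNN:
    """The eight-block network with named layers.

    ``forward(x)`` returns the class scores for a batch (N, 3, 224, 224);
    ``activations(x, layer)`` returns the flattened per-image activation
    of any named layer, e.g. ``"relu8"`` for the 37,632-unit analysis
    layer.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.convs, self.bns = [], []
        c_in = 3
        for c, k in zip(spec.channels, spec.kernels):
            self.convs.append(_Conv(c_in, c, k, rng))
            self.bns.append(_BatchNorm(c))
            c_in = c
        self.fc = _Linear(spec.channels[-1], spec.n_classes, rng)

    # -- forward ----------------------------------------------------------
    def _iter_layers(self, x):
        """Yield (name, activation) through the network for one batch."""
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns), start=1):
            x = conv(x)
            yield f"conv{i}", x
            x = bn(x)
            yield f"bn{i}", x
            x = np.maximum(x, 0.0)
            yield f"relu{i}", x
            if i <= self.spec.n_pooled_blocks:
                x = _maxpool2(x)
                yield f"pool{i}", x
        x = x.mean(axis=(2, 3), keepdims=True)
        yield "avgpool", x
        x = self.fc(x.reshape(x.shape[0], -1))
        yield "fc", x

    def forward(self, x: np.ndarray, upto: str | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        out = None
        for name, act in self._iter_layers(x):
            out = act
            if name == upto:
                return act
        if upto is not None:
            raise KeyError(f"no layer named {upto!r}")
        return out

    def activations(
        self, x: np.ndarray, layer: str | None = None, batch_size: int = 4
    ) -> np.ndarray:
        """Flattened activations (n_images, n_units) at a named layer."""
        layer = layer or self.spec.analysis_layer
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        chunks = []
        for i in range(0, x.shape[0], batch_size):
            a = self.forward(x[i : i + batch_size], upto=layer)
            chunks.append(a.reshape(a.shape[0], -1))
        return np.concatenate(chunks, axis=0)

    def forward_shapes(self, n: int = 1) -> "OrderedDict[str, tuple]":
        """Observed per-layer shapes from an actual forward pass."""
        x = np.zeros((n, 3, self.spec.input_size, self.spec.input_size),
                     dtype=np.float32)
        return OrderedDict(
            (name, act.shape[1:]) for name, act in self._iter_layers(x)
        )

    # -- weights ----------------------------------------------------------
    def _param_dict(self):
        d = {}
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns), start=1):
            for k, v in conv.params().items():
                d[f"conv{i}.{k}"] = v
            for k, v in bn.params().items():
                d[f"bn{i}.{k}"] = v
        for k, v in self.fc.params().items():
            d[f"fc.{k}"] = v
        return d

    def save_weights(self, path) -> None:
        np.savez(path, **self._param_dict())

    def load_weights(self, path) -> None:
        with np.load(path) as npz:
            ckpt = {k: npz[k] for k in npz.files}
        own = self._param_dict()
        missing = sorted(set(own) - set(ckpt))
        unexpected = sorted(set(ckpt) - set(own))
        bad_shape = sorted(
            k for k in set(own) & set(ckpt) if own[k].shape != ckpt[k].shape
        )
        if missing or unexpected or bad_shape:
            raise CheckpointError(
                f"checkpoint mismatch: missing={missing} "
                f"unexpected={unexpected} shape_mismatch={bad_shape}"
            )
        for k, arr in ckpt.items():
            own[k][...] = arr


def build_architecture(
    spec: ArchitectureSpec | None = None,
    seed: int = 0,
    weights: str | None = None,
) -> OrdinalityCNN:
    """Build the network; random init unless a checkpoint path is given."""
    model = OrdinalityCNN(spec or ArchitectureSpec(), seed=seed)
    if weights is not None:
        model.load_weights(weights)
    return model
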