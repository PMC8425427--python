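"""The residual contact network, with hand-written numpy forward/backward.

Architecture (single sample, variable length L):

* 1D stack: six pre-activation residual blocks (kernel 17) over the (31, L)
  sequential features, filter counts rising 35..60, then a 1x1 convolution
  compressing to 2 channels;
* outer concatenation: the compressed per-residue vectors v are broadcast to
  pairwise planes [v_i ; v_j] (4 planes), each averaged with its transpose;
* 2D stack: 36 pre-activation residual blocks (3x3 kernels) in nine filter
  groups (32, 32, 48, 64, 64, 64, 48, 32, 32) over the concatenation of the
  outer planes with the four pairwise input channels;
* output block: normalization, ELU, 1x1 convolution, sigmoid.

A pre-activation ("v2") block is norm -> ELU -> conv, twice, plus a shortcut;
a 1x1 projection aligns the shortcut when the channel count changes.  All
convolutions are zero-padded and size-preserving, so the network accepts any
L.  Normalization uses per-channel statistics over the spatial axes of the
(single) sample, which keeps inference deterministic and length-independent.

Every layer implements ``forward``/``backward`` explicitly; gradients are
exact (validated against finite differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureBundle

_EPS = 1e-5


class Param:
    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = False):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay  # True for convolution kernels (L2 weight decay)


class Layer:
    def params(self):
        return []


class Conv1d(Layer):
    """Size-preserving 1D convolution on (C_in, L) tensors."""

    def __init__(self, cin, cout, k, rng):
        std = np.sqrt(2.0 / (cin * k))
        self.w = Param(rng.normal(0.0, std, size=(cout, cin, k)), decay=True)
        self.b = Param(np.zeros(cout))
        self.k = k

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        k = self.k
        cin, L = x.shape
        xp = np.zeros((cin, L + k - 1))
        xp[:, (k - 1) // 2:(k - 1) // 2 + L] = x
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (cin, L, k)
        cols = cols.transpose(0, 2, 1).reshape(cin * k, L)
        self._cols, self._L = cols, L
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        return wmat @ cols + self.b.value[:, None]

    def backward(self, dy):
        k, L = self.k, self._L
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        self.w.grad += (dy @ self._cols.T).reshape(self.w.value.shape)
        self.b.grad += dy.sum(axis=1)
        dcols = (wmat.T @ dy).reshape(self.w.value.shape[1], k, L)
        cin = dcols.shape[0]
        dxp = np.zeros((cin, L + k - 1))
        for o in range(k):
            dxp[:, o:o + L] += dcols[:, o, :]
        return dxp[:, (k - 1) // 2:(k - 1) // 2 + L]


class Conv2d(Layer):
    """Size-preserving 2D convolution on (C_in, H, W) tensors."""

    def __init__(self, cin, cout, k, rng):
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, std, size=(cout, cin, k, k)), decay=True)
        self.b = Param(np.zeros(cout))
        self.k = k

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        k = self.k
        cin, H, W = x.shape
        p = (k - 1) // 2
        xp = np.zeros((cin, H + k - 1, W + k - 1))
        xp[:, p:p + H, p:p + W] = x
        cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = cols.transpose(0, 3, 4, 1, 2).reshape(cin * k * k, H * W)
        self._cols, self._shape = cols, (H, W)
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        y = wmat @ cols + self.b.value[:, None]
        return y.reshape(-1, H, W)

    def backward(self, dy):
        k = self.k
        H, W = self._shape
        p = (k - 1) // 2
        dyf = dy.reshape(dy.shape[0], H * W)
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        self.w.grad += (dyf @ self._cols.T).reshape(self.w.value.shape)
        self.b.grad += dyf.sum(axis=1)
        dcols = (wmat.T @ dyf).reshape(self.w.value.shape[1], k, k, H, W)
        cin = dcols.shape[0]
        dxp = np.zeros((cin, H + k - 1, W + k - 1))
        for a in range(k):
            for b in range(k):
                dxp[:, a:a + H, b:b + W] += dcols[:, a, b]
        return dxp[:, p:p + H, p:p + W]


class Norm(Layer):
    """Per-channel normalization over the spatial axes of the sample."""

    def __init__(self, c):
        self.g = Param(np.ones(c))
        self.b = Param(np.zeros(c))

    def params(self):
        return [self.g, self.b]

    def forward(self, x, train=False):
        axes = tuple(range(1, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        std = np.sqrt(var + _EPS)
        xhat = (x - mu) / std
        self._cache = (xhat, std, axes)
        shape = (-1,) + (1,) * (x.ndim - 1)
        return self.g.value.reshape(shape) * xhat + self.b.value.reshape(shape)

    def backward(self, dy):
        xhat, std, axes = self._cache
        n = np.prod([xhat.shape[a] for a in axes])
        self.g.grad += (dy * xhat).sum(axis=axes)
        self.b.grad += dy.sum(axis=axes)
        shape = (-1,) + (1,) * (xhat.ndim - 1)
        dxhat = dy * self.g.value.reshape(shape)
        return (dxhat - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)) / std


class ELU(Layer):
    def forward(self, x, train=False):
        y = np.where(x > 0, x, np.expm1(x))
        self._cache = (x, y)
        return y

    def backward(self, dy):
        x, y = self._cache
        return dy * np.where(x > 0, 1.0, y + 1.0)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ResBlock(Layer):
    """Pre-activation residual block (norm -> ELU -> conv, twice)."""

    def __init__(self, cin, cout, k, rng, ndim):
        conv = Conv1d if ndim == 1 else Conv2d
        self.body = Sequential([
            Norm(cin), ELU(), conv(cin, cout, k, rng),
            Norm(cout), ELU(), conv(cout, cout, k, rng),
        ])
        self.proj = conv(cin, cout, 1, rng) if cin != cout else None

    def params(self):
        ps = self.body.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x, train=False):
        h = self.body.forward(x, train)
        s = x if self.proj is None else self.proj.forward(x, train)
        return h + s

    def backward(self, dy):
        ds = dy if self.proj is None else self.proj.backward(dy)
        dx = self.body.backward(dy)
        return dx + ds


@dataclass
class NetworkConfig:
    conv1d_kernel: int = 17
    filters_1d: tuple = (35, 40, 45, 50, 55, 60)
    compress_filters: int = 2
    filters_2d_groups: tuple = (32, 32, 48, 64, 64, 64, 48, 32, 32)
    blocks_per_group: int = 4
    conv2d_kernel: int = 3
    seq_channels: int = 31
    pair_channels: int = 4

    @property
    def filters_2d(self) -> tuple:
        return tuple(f for f in self.filters_2d_groups
                     for _ in range(self.blocks_per_group))


FULL_CONFIG = NetworkConfig()
TINY_CONFIG = NetworkConfig(filters_1d=(16, 16), filters_2d_groups=(16, 16),
                            blocks_per_group=2)


class _OuterConcat(Layer):
    """Per-residue vectors (2, L) -> symmetric pairwise planes (4, L, L)."""

    def forward(self, v, train=False):
        c, L = v.shape
        self._shape = (c, L)
        planes = np.empty((2 * c, L, L))
        planes[:c] = v[:, :, None] * np.ones((1, 1, L))   # row copy: v_i
        planes[c:] = v[:, None, :] * np.ones((1, L, 1))   # col copy: v_j
        return (planes + planes.transpose(0, 2, 1)) / 2.0

    def backward(self, dy):
        c, L = self._shape
        dsym = (dy + dy.transpose(0, 2, 1)) / 2.0
        return dsym[:c].sum(axis=2) + dsym[c:].sum(axis=1)


class ContactNetwork:
    """Full model: 1D stack -> outer concatenation -> 2D stack -> sigmoid."""

    def __init__(self, cfg: NetworkConfig = FULL_CONFIG, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        k1 = cfg.conv1d_kernel
        blocks1, cin = [], cfg.seq_channels
        for f in cfg.filters_1d:
            blocks1.append(ResBlock(cin, f, k1, rng, ndim=1))
            cin = f
        blocks1.append(Conv1d(cin, cfg.compress_filters, 1, rng))
        self.stack1d = Sequential(blocks1)
        self.outer = _OuterConcat()

        c2in = 2 * cfg.compress_filters + cfg.pair_channels
        blocks2, cin = [], c2in
        for f in cfg.filters_2d:
            blocks2.append(ResBlock(cin, f, cfg.conv2d_kernel, rng, ndim=2))
            cin = f
        self.stack2d = Sequential(blocks2)
        self.head = Sequential([Norm(cin), ELU(), Conv2d(cin, 1, 1, rng)])

    # -- parameters -------------------------------------------------------
    def params(self):
        return (self.stack1d.params() + self.stack2d.params()
                + self.head.params())

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self):
        for p in self.params():
            p.grad[:] = 0.0

    # -- forward / backward ----------------------------------------------
    def forward(self, bundle: FeatureBundle, train: bool = False) -> np.ndarray:
        """Contact probability matrix (L, L), entries strictly in (0, 1)."""
        x1 = np.ascontiguousarray(bundle.seq_features.T, dtype=float)
        v = self.stack1d.forward(x1, train)
        planes = self.outer.forward(v, train)
        x2 = np.concatenate([planes, bundle.pair_features.astype(float)], axis=0)
        self._n_outer = planes.shape[0]
        h = self.stack2d.forward(x2, train)
        z = self.head.forward(h, train)[0]
        p = 1.0 / (1.0 + np.exp(-z))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        self._p = p
        return p

    def backward(self, dp: np.ndarray) -> None:
        """Accumulate parameter gradients given d(loss)/d(probability)."""
        p = self._p
        dz = dp * p * (1.0 - p)
        dh = self.head.backward(dz[None, :, :])
        dx2 = self.stack2d.backward(dh)
        dplanes = dx2[:self._n_outer]
        dv = self.outer.backward(dplanes)
        self.stack1d.backward(dv)

    def predict_map(self, bundle: FeatureBundle) -> np.ndarray:
        """Inference: forward pass followed by output symmetrization."""
        p = self.forward(bundle, train=False)
        return (p + p.T) / 2.0
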