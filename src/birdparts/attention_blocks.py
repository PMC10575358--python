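"""Convolutional attention blocks: CBAM and the Res2Net-CBAM residual unit.

Channel attention
    ``Mc(F) = sigmoid(W1·relu(W0·avgpool(F)) + W1·relu(W0·maxpool(F)))``
    with the MLP (W0, W1) shared between the global-average and global-max
    pooled channel descriptors.

Spatial attention
    ``Ms(F) = sigmoid(conv7x7([mean_c(F); max_c(F)]))`` — channel-wise mean
    and max maps stacked to 2 channels, reduced to 1 by a 7×7 convolution
    (padding 3), sigmoid-normalised.

CBAM applies the two sequentially and multiplicatively:
``F' = Mc(F) ⊗ F`` then ``F'' = Ms(F') ⊗ F'``.

The Res2Net-CBAM unit splits the feature map after a 1×1 entry convolution
into ``s`` channel groups and chains 3×3 convolutions hierarchically
(``Y1 = X1``, ``Y2 = K2(X2)``, ``Yi = Ki(Xi + Y(i-1))`` for ``i ≥ 3``),
concatenates, applies a 1×1 exit convolution, then CBAM, then adds the block
input back as a residual: ``F = Ms(F1) ⊗ F1 + X`` with ``F1 = Mc(Y) ⊗ Y``.

Two surfaces are provided: :class:`Module` layers operating on batched
``(N, C, H, W)`` tensors inside the detector, and functional wrappers taking
single ``(C, H, W)`` numpy arrays with explicit parameter bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, no_grad
from .nn import Conv, Conv2d, Module, ModuleList, kaiming


class ChannelAttention(Module):
    """Per-channel gate from global average- and max-pooled descriptors.

    reduction ratio ``r`` is capped so the hidden width is at least 1.
    """

    def __init__(self, c: int, r: int = 16):
        super().__init__()
        hidden = max(c // r, 1)
        self.c = c
        self.w0 = Tensor(kaiming((hidden, c), c), requires_grad=True)
        self.w1 = Tensor(kaiming((c, hidden), hidden), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3)).reshape(n, c)
        mx = x.max(axis=3).max(axis=2).reshape(n, c)
        out = None
        for desc in (avg, mx):
            h = desc.matmul(self.w0.transpose(1, 0)).relu()
            o = h.matmul(self.w1.transpose(1, 0))
            out = o if out is None else out + o
        return out.sigmoid().reshape(n, c, 1, 1)


class SpatialAttention(Module):
    """Single-channel spatial gate from stacked channel-mean/max maps."""

    def __init__(self, k: int = 7):
        super().__init__()
        self.conv = Conv2d(2, 1, k, 1, k // 2, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(Tensor.concat([avg, mx], axis=1)).sigmoid()


class CBAM(Module):
    """Sequential channel then spatial attention, applied multiplicatively."""

    def __init__(self, c: int, r: int = 16, k: int = 7):
        super().__init__()
        self.ca = ChannelAttention(c, r)
        self.sa = SpatialAttention(k)

    def forward(self, x: Tensor) -> Tensor:
        x = x * self.ca(x)
        return x * self.sa(x)


class Res2NetCBAM(Module):
    """Hierarchical multi-scale residual unit with CBAM re-weighting.

    Input and output channel counts must match for the residual addition; the
    internal width equals the input width and must be divisible by ``scale``.
    Convolutions carry BN + SiLU like the rest of the detector; the attention
    convolutions are sigmoid-only.
    """

    def __init__(self, c1: int, c2: int, scale: int = 4, r: int = 16):
        super().__init__()
        if c1 != c2:
            raise ValueError(f"residual unit needs equal in/out channels, got {c1}/{c2}")
        if c2 % scale != 0:
            raise ValueError(f"channels {c2} not divisible by scale {scale}")
        self.scale = scale
        self.width = c2 // scale
        self.cv1 = Conv(c1, c2, 1, 1)
        self.convs = ModuleList([Conv(self.width, self.width, 3, 1)
                                 for _ in range(scale - 1)])
        self.cv2 = Conv(c2, c2, 1, 1)
        self.cbam = CBAM(c2, r)

    def forward(self, x: Tensor) -> Tensor:
        z = self.cv1(x)
        w = self.width
        groups = [z[:, i * w:(i + 1) * w] for i in range(self.scale)]
        ys = [groups[0]]
        prev = None
        for i in range(1, self.scale):
            inp = groups[i] if prev is None else groups[i] + prev
            prev = self.convs[i - 1](inp)
            ys.append(prev)
        y = self.cv2(Tensor.concat(ys, axis=1)) if self.scale > 1 else self.cv2(ys[0])
        return self.cbam(y) + x


# ---------------------------------------------------------------------------
# Functional surface on (C, H, W) arrays with explicit parameter bundles.
# ---------------------------------------------------------------------------

@dataclass
class ChannelAttentionParams:
    """Shared two-layer MLP weights: w0 maps C -> C/r, w1 maps C/r -> C."""

    w0: np.ndarray
    w1: np.ndarray

    def __post_init__(self):
        hidden, c = self.w0.shape
        if self.w1.shape != (c, hidden):
            raise ValueError("w0/w1 shapes do not compose to a C -> C map")

    @property
    def channels(self) -> int:
        return self.w0.shape[1]

    @classmethod
    def random(cls, c: int, r: int = 16, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(c // r, 1)
        return cls(w0=rng.standard_normal((hidden, c)) / np.sqrt(c),
                   w1=rng.standard_normal((c, hidden)) / np.sqrt(hidden))


@dataclass
class SpatialAttentionParams:
    """7×7 convolution kernel, shape (1, 2, 7, 7), applied with padding 3."""

    kernel: np.ndarray

    def __post_init__(self):
        if self.kernel.shape[0] != 1 or self.kernel.shape[1] != 2:
            raise ValueError("spatial attention kernel must be (1, 2, k, k)")

    @classmethod
    def random(cls, k: int = 7, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        return cls(kernel=rng.standard_normal((1, 2, k, k)) / np.sqrt(2 * k * k))


@dataclass
class Res2NetCbamParams:
    """Weights of one Res2Net-CBAM unit (BN at identity statistics).

    entry/exit are 1×1 kernels of shape (C, C, 1, 1); ``groups`` holds the
    ``scale − 1`` hierarchical 3×3 kernels of shape (w, w, 3, 3), w = C/scale.
    """

    scale: int
    entry: np.ndarray
    groups: list
    exit: np.ndarray
    cbam: tuple = field(default=None)  # (ChannelAttentionParams, SpatialAttentionParams)

    @classmethod
    def random(cls, c: int, scale: int = 4, r: int = 16,
               rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if c % scale:
            raise ValueError(f"channels {c} not divisible by scale {scale}")
        w = c // scale
        return cls(
            scale=scale,
            entry=rng.standard_normal((c, c, 1, 1)) / np.sqrt(c),
            groups=[rng.standard_normal((w, w, 3, 3)) / np.sqrt(9 * w)
                    for _ in range(scale - 1)],
            exit=rng.standard_normal((c, c, 1, 1)) / np.sqrt(c),
            cbam=(ChannelAttentionParams.random(c, r, rng),
                  SpatialAttentionParams.random(7, rng)),
        )


def _chw(feature_map: np.ndarray) -> np.ndarray:
    f = np.asarray(feature_map, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError("feature map must be (C, H, W)")
    return f


def channel_attention(feature_map: np.ndarray,
                      params: ChannelAttentionParams) -> np.ndarray:
    """Per-channel attention weights, a C-vector with entries in (0, 1)."""
    f = _chw(feature_map)
    c = f.shape[0]
    if params.channels != c:
        raise ValueError(f"params expect {params.channels} channels, map has {c}")
    mod = ChannelAttention(c, r=max(c // params.w0.shape[0], 1))
    mod.w0.data = params.w0.astype(np.float64)
    mod.w1.data = params.w1.astype(np.float64)
    with no_grad():
        out = mod.eval()(Tensor(f[None]))
    return out.data.reshape(c)


def spatial_attention(feature_map: np.ndarray,
                      params: SpatialAttentionParams) -> np.ndarray:
    """Spatial attention map, shape (H, W), entries in (0, 1)."""
    f = _chw(feature_map)
    mod = SpatialAttention(k=params.kernel.shape[-1])
    mod.conv.weight.data = params.kernel.astype(np.float64)
    with no_grad():
        out = mod.eval()(Tensor(f[None]))
    return out.data.reshape(f.shape[1], f.shape[2])


def cbam(feature_map: np.ndarray, ca_params: ChannelAttentionParams,
         sa_params: SpatialAttentionParams) -> np.ndarray:
    """Apply channel then spatial attention to a (C, H, W) map."""
    f = _chw(feature_map)
    fc = f * channel_attention(f, ca_params)[:, None, None]
    return fc * spatial_attention(fc, sa_params)[None]


def res2net_cbam(feature_map: np.ndarray, params: Res2NetCbamParams) -> np.ndarray:
    """Run one Res2Net-CBAM unit on a (C, H, W) map (identity BN statistics)."""
    f = _chw(feature_map)
    c = f.shape[0]
    mod = Res2NetCBAM(c, c, scale=params.scale,
                      r=max(c // params.cbam[0].w0.shape[0], 1))
    mod.cv1.conv.weight.data = params.entry.astype(np.float64)
    for blk, w in zip(mod.convs, params.groups):
        blk.conv.weight.data = w.astype(np.float64)
    mod.cv2.conv.weight.data = params.exit.astype(np.float64)
    mod.cbam.ca.w0.data = params.cbam[0].w0.astype(np.float64)
    mod.cbam.ca.w1.data = params.cbam[0].w1.astype(np.float64)
    mod.cbam.sa.conv.weight.data = params.cbam[1].kernel.astype(np.float64)
    for m in mod.modules():
        if hasattr(m, "running_mean"):
            m.running_mean = m.running_mean.astype(np.float64)
            m.running_var = m.running_var.astype(np.float64)
            m.gamma.data = m.gamma.data.astype(np.float64)
            m.beta.data = m.beta.data.astype(np.float64)
    with no_grad():
        out = mod.eval()(Tensor(f[None]))
    return out.data[0]
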