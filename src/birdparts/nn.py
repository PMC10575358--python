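"""Layer library for the part detector.

Implements the building blocks of a YOLOv5-6.0-style single-stage detector on
the numpy autodiff engine: Conv (conv + batchnorm + SiLU), the C3 cross-stage
block, SPPF fast spatial pyramid pooling, nearest upsampling, concatenation and
the anchor-based Detect head.  Attention blocks live in
:mod:`birdparts.attention_blocks`.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Module:
    """Base class: tracks parameter tensors and submodules by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, ModuleList):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix=""):
        for k, v in self._params.items():
            yield (f"{prefix}{k}", v)
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{k}.")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self):
        state = {name: p.data for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = m.running_mean
                state[f"__bn{i}.running_var"] = m.running_var
        return state

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"__bn{i}.running_mean"])
                m.running_var = np.asarray(state[f"__bn{i}.running_var"])

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


_global_rng = np.random.default_rng(0)


def set_init_rng(rng: np.random.Generator):
    """Set the generator used for weight initialisation (seeded builds)."""
    global _global_rng
    _global_rng = rng


def kaiming(shape, fan_in, dtype=np.float32):
    std = math_sqrt(2.0 / fan_in)
    return (_global_rng.standard_normal(shape, dtype=np.float32) * std).astype(dtype)


def math_sqrt(x):
    return float(np.sqrt(x))


def autopad(k: int) -> int:
    return k // 2


class Conv2d(Module):
    def __init__(self, c1, c2, k=1, s=1, p=None, bias=True):
        super().__init__()
        self.k, self.s = k, s
        self.p = autopad(k) if p is None else p
        self.weight = Tensor(kaiming((c2, c1, k, k), c1 * k * k), requires_grad=True)
        self.bias = Tensor(np.zeros(c2, dtype=np.float32), requires_grad=True) if bias else None
        if bias:
            self._params["bias"] = self.bias

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.s, padding=self.p)


class BatchNorm2d(Module):
    # eps/momentum follow the YOLOv5 convention, except momentum is raised so
    # running statistics settle within a few hundred desk-scale steps
    def __init__(self, c, eps=1e-3, momentum=0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.size / c
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(c))
            unbiased = var.data.reshape(c) * (n / max(n - 1, 1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
            xhat = xc * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(1, c, 1, 1).astype(x.dtype)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1).astype(x.dtype)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, c, 1, 1)
        b = self.beta.reshape(1, c, 1, 1)
        return xhat * g + b


class Conv(Module):
    """Standard detector convolution block: Conv2d (no bias) + BN + SiLU."""

    def __init__(self, c1, c2, k=1, s=1, p=None):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, s, p, bias=False)
        self.bn = BatchNorm2d(c2)

    def forward(self, x):
        return self.bn(self.conv(x)).silu()


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, e=0.5):
        super().__init__()
        c_ = max(int(c2 * e), 1)
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv(c_, c2, 3, 1)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """Cross-stage partial block with n bottlenecks."""

    def __init__(self, c1, c2, n=1, shortcut=True, e=0.5):
        super().__init__()
        c_ = max(int(c2 * e), 1)
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv(c1, c_, 1, 1)
        self.cv3 = Conv(2 * c_, c2, 1, 1)
        self.m = ModuleList([Bottleneck(c_, c_, shortcut, 1.0) for _ in range(n)])

    def forward(self, x):
        y1 = self.cv1(x)
        for b in self.m:
            y1 = b(y1)
        y2 = self.cv2(x)
        return self.cv3(Tensor.concat([y1, y2], axis=1))


class SPPF(Module):
    """Fast spatial pyramid pooling: three serial k×k max-pools, concatenated."""

    def __init__(self, c1, c2, k=5):
        super().__init__()
        c_ = c1 // 2
        self.k = k
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv(c_ * 4, c2, 1, 1)

    def forward(self, x):
        x = self.cv1(x)
        y1 = x.maxpool2d(self.k, 1, self.k // 2)
        y2 = y1.maxpool2d(self.k, 1, self.k // 2)
        y3 = y2.maxpool2d(self.k, 1, self.k // 2)
        return self.cv2(Tensor.concat([x, y1, y2, y3], axis=1))


class Upsample(Module):
    def __init__(self, scale=2):
        super().__init__()
        if scale != 2:
            raise ValueError("only 2x nearest upsampling is supported")

    def forward(self, x):
        return x.upsample_nearest2()


class Concat(Module):
    def __init__(self, axis=1):
        super().__init__()
        self.axis = axis

    def forward(self, xs):
        return Tensor.concat(xs, axis=self.axis)


class Detect(Module):
    """Anchor-based detection head over three feature scales.

    Emits, per scale, a raw grid of shape (N, na, H, W, nc + 5): box offsets
    (4), objectness (1) and one logit per class.
    """

    def __init__(self, nc, anchors, ch):
        super().__init__()
        self.nc = nc
        self.no = nc + 5
        self.anchors = np.asarray(anchors, dtype=np.float32).reshape(len(ch), -1, 2)
        self.na = self.anchors.shape[1]
        self.m = ModuleList([Conv2d(c, self.no * self.na, 1, bias=True) for c in ch])

    def forward(self, xs):
        out = []
        for conv, x in zip(self.m, xs):
            N, _, H, W = x.shape
            y = conv(x).reshape(N, self.na, self.no, H, W).transpose(0, 1, 3, 4, 2)
            out.append(y)
        return out
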