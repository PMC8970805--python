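"""Numpy neural-network primitives with explicit forward/backward passes.

All activations are (N, C, H, W) arrays; convolutions use im2col via
``sliding_window_view`` plus einsum.  Each layer caches what its backward pass
needs; parameter gradients accumulate in ``Param.grad``.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> List[Param]:
        return []


class Conv2D(Layer):
    """3x3 / 1x1 convolution, 'same' padding, optional stride (He init)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int,
                 rng: np.random.Generator, name: str = "conv"):
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, std, size=(cout, cin, k, k)), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self.k, self.stride = k, stride
        self._cache = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        pad = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        v = v[:, :, ::s, ::s]  # (N, Cin, Ho, Wo, k, k)
        out = np.einsum("nchwij,ocij->nohw", v, self.W.value, optimize=True)
        out += self.b.value[None, :, None, None]
        self._cache = (x.shape, v)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        (n, cin, h, w), v = self._cache
        k, s = self.k, self.stride
        pad = (k - 1) // 2
        self.W.grad += np.einsum("nchwij,nohw->ocij", v, g, optimize=True)
        self.b.grad += g.sum(axis=(0, 2, 3))
        ho, wo = g.shape[2], g.shape[3]
        dxp = np.zeros((n, cin, h + 2 * pad, w + 2 * pad))
        for ki in range(k):
            for kj in range(k):
                contrib = np.einsum("nohw,oc->nchw", g,
                                    self.W.value[:, :, ki, kj], optimize=True)
                dxp[:, :, ki:ki + ho * s:s, kj:kj + wo * s:s] += contrib
        return dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp


class BatchNorm2D(Layer):
    """Per-channel batch normalization with learnable affine and running
    statistics (exponential average, used in eval mode)."""

    def __init__(self, c: int, name: str = "bn", momentum: float = 0.9,
                 eps: float = 1e-5):
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self.training = False

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> List[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[:] = (self.momentum * self.running_mean
                                    + (1 - self.momentum) * mean)
            self.running_var[:] = (self.momentum * self.running_var
                                   + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self.gamma.grad += np.sum(g * xhat, axis=(0, 2, 3))
        self.beta.grad += np.sum(g, axis=(0, 2, 3))
        dxhat = g * self.gamma.value[None, :, None, None]
        if not self.training:
            return dxhat * invstd[None, :, None, None]
        n = g.shape[0] * g.shape[2] * g.shape[3]
        s1 = np.sum(dxhat, axis=(0, 2, 3))[None, :, None, None]
        s2 = np.sum(dxhat * xhat, axis=(0, 2, 3))[None, :, None, None]
        return (invstd[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    """Rectifier with an optional leaky slope (guards against dead units)."""

    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._scale = np.where(x > 0, 1.0, self.slope)
        return x * self._scale

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._scale


class UpsampleNearest2x(Layer):
    """Nearest-neighbour x2 upsampling, cropped to an explicit target size."""

    def forward(self, x: np.ndarray, target_hw: Tuple[int, int]) -> np.ndarray:
        self._in_hw = x.shape[2:]
        self._target = target_hw
        up = x.repeat(2, axis=2).repeat(2, axis=3)
        return up[:, :, :target_hw[0], :target_hw[1]]

    def backward(self, g: np.ndarray) -> np.ndarray:
        h2, w2 = 2 * self._in_hw[0], 2 * self._in_hw[1]
        gh, gw = g.shape[2], g.shape[3]
        if (gh, gw) != (h2, w2):
            g = np.pad(g, ((0, 0), (0, 0), (0, h2 - gh), (0, w2 - gw)))
        n, c = g.shape[:2]
        g = g.reshape(n, c, self._in_hw[0], 2, self._in_hw[1], 2)
        return g.sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 name: str = "dense"):
        std = np.sqrt(2.0 / cin)
        self.W = Param(rng.normal(0.0, std, size=(cin, cout)), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


class BasicBlock(Layer):
    """conv-bn-relu-conv-bn with identity (or projected) skip, relu after add."""

    def __init__(self, cin: int, cout: int, stride: int,
                 rng: np.random.Generator, name: str = "block"):
        self.conv1 = Conv2D(cin, cout, 3, stride, rng, f"{name}.conv1")
        self.bn1 = BatchNorm2D(cout, f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2D(cout, cout, 3, 1, rng, f"{name}.conv2")
        self.bn2 = BatchNorm2D(cout, f"{name}.bn2")
        self.proj: Optional[Conv2D] = None
        if stride != 1 or cin != cout:
            self.proj = Conv2D(cin, cout, 1, stride, rng, f"{name}.proj")
            self.bn_proj = BatchNorm2D(cout, f"{name}.bn_proj")
        self.relu_out = ReLU()

    def sublayers(self) -> List[Layer]:
        out = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            out += [self.proj, self.bn_proj]
        return out

    def params(self) -> List[Param]:
        return [p for l in self.sublayers() for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.bn1.forward(self.conv1.forward(x))
        y = self.bn2.forward(self.conv2.forward(self.relu1.forward(y)))
        if self.proj is not None:
            skip = self.bn_proj.forward(self.proj.forward(x))
        else:
            skip = x
        return self.relu_out.forward(y + skip)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(g)
        gy = self.bn2.backward(g)
        gy = self.conv2.backward(gy)
        gy = self.relu1.backward(gy)
        gy = self.bn1.backward(gy)
        gx_main = self.conv1.backward(gy)
        if self.proj is not None:
            gx_skip = self.proj.backward(self.bn_proj.backward(g))
        else:
            gx_skip = g
        return gx_main + gx_skip


class BottleneckBlock(Layer):
    """1x1 reduce -> 3x3 -> 1x1 expand (x4), batch-normalized, projected skip."""

    EXPANSION = 4

    def __init__(self, cin: int, planes: int, stride: int,
                 rng: np.random.Generator, name: str = "bneck"):
        cout = planes * self.EXPANSION
        self.conv1 = Conv2D(cin, planes, 1, 1, rng, f"{name}.conv1")
        self.bn1 = BatchNorm2D(planes, f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2D(planes, planes, 3, stride, rng, f"{name}.conv2")
        self.bn2 = BatchNorm2D(planes, f"{name}.bn2")
        self.relu2 = ReLU()
        self.conv3 = Conv2D(planes, cout, 1, 1, rng, f"{name}.conv3")
        self.bn3 = BatchNorm2D(cout, f"{name}.bn3")
        self.proj: Optional[Conv2D] = None
        if stride != 1 or cin != cout:
            self.proj = Conv2D(cin, cout, 1, stride, rng, f"{name}.proj")
            self.bn_proj = BatchNorm2D(cout, f"{name}.bn_proj")
        self.relu_out = ReLU()
        self.cout = cout

    def sublayers(self) -> List[Layer]:
        out = [self.conv1, self.bn1, self.conv2, self.bn2, self.conv3, self.bn3]
        if self.proj is not None:
            out += [self.proj, self.bn_proj]
        return out

    def params(self) -> List[Param]:
        return [p for l in self.sublayers() for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        y = self.relu2.forward(self.bn2.forward(self.conv2.forward(y)))
        y = self.bn3.forward(self.conv3.forward(y))
        if self.proj is not None:
            skip = self.bn_proj.forward(self.proj.forward(x))
        else:
            skip = x
        return self.relu_out.forward(y + skip)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(g)
        gy = self.conv3.backward(self.bn3.backward(g))
        gy = self.conv2.backward(self.bn2.backward(self.relu2.backward(gy)))
        gx_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(gy)))
        if self.proj is not None:
            gx_skip = self.proj.backward(self.bn_proj.backward(g))
        else:
            gx_skip = g
        return gx_main + gx_skip


__all__ = ["Param", "Layer", "Conv2D", "BatchNorm2D", "ReLU",
           "UpsampleNearest2x", "GlobalAvgPool", "Dense", "BasicBlock",
           "BottleneckBlock"]
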